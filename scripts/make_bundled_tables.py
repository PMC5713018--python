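"""One-off generator for the bundled data tables under src/shallowsea/data/."""
import numpy as np
import os

OUT = os.path.join(os.path.dirname(__file__), "..", "src", "shallowsea", "data")
os.makedirs(OUT, exist_ok=True)

grid = np.arange(400, 1051, 5)

# --- WV-2-like band definitions (nominal intervals; boxcar responses built at load) ---
bands = [
    # name, center, min, max, K (W m-2 sr-1 um-1 per count), delta_lambda (um)
    ("coastal", 427, 400, 450, 9.295654e-03, 0.0473),
    ("blue", 478, 450, 510, 1.783568e-02, 0.0543),
    ("green", 546, 510, 580, 1.364197e-02, 0.0630),
    ("yellow", 608, 585, 625, 6.810718e-03, 0.0374),
    ("red", 659, 630, 690, 1.851735e-02, 0.0574),
    ("rededge", 724, 705, 745, 5.862800e-03, 0.0393),
    ("nir1", 831, 770, 895, 2.021583e-02, 0.0989),
    ("nir2", 908, 860, 1040, 9.042234e-03, 0.0996),
]
with open(os.path.join(OUT, "wv2_bands.tsv"), "w") as f:
    f.write("# WV-2-like band metadata: boxcar responses over [min_nm, max_nm]\n")
    f.write("band\tcenter_nm\tmin_nm\tmax_nm\tK\tdelta_lambda_um\n")
    for row in bands:
        f.write("\t".join(str(v) for v in row) + "\n")

# --- Pure-seawater absorption (m-1): standard published values at coarse nodes,
#     linearly interpolated to the 5-nm grid. NIR (>900 nm) values are approximate;
#     water there is essentially opaque for shallow-water work.
aw_nodes = {
    400: 0.00663, 410: 0.00473, 420: 0.00454, 430: 0.00495, 440: 0.00635,
    450: 0.00922, 460: 0.00979, 470: 0.0106, 480: 0.0127, 490: 0.0150,
    500: 0.0204, 510: 0.0325, 520: 0.0409, 530: 0.0434, 540: 0.0474,
    550: 0.0565, 560: 0.0619, 570: 0.0695, 580: 0.0896, 590: 0.1351,
    600: 0.2224, 610: 0.2644, 620: 0.2755, 630: 0.2916, 640: 0.3108,
    650: 0.340, 660: 0.410, 670: 0.439, 680: 0.465, 690: 0.516,
    700: 0.624, 710: 0.827, 720: 1.231, 730: 1.799, 740: 2.38,
    750: 2.47, 760: 2.55, 770: 2.51, 780: 2.36, 790: 2.16,
    800: 2.07, 810: 2.33, 820: 2.89, 830: 3.64, 840: 4.45,
    850: 4.59, 860: 4.61, 870: 5.10, 880: 5.93, 890: 7.30,
    900: 7.00, 910: 8.00, 920: 11.0, 930: 17.0, 940: 26.0,
    950: 32.0, 960: 40.0, 970: 45.0, 980: 43.0, 990: 41.0,
    1000: 36.0, 1010: 31.0, 1020: 26.0, 1030: 22.0, 1040: 19.0, 1050: 17.0,
}
lam_nodes = np.array(sorted(aw_nodes))
aw = np.interp(grid, lam_nodes, np.array([aw_nodes[k] for k in lam_nodes]))
# Pure-seawater backscatter: Morel-style power law, bbw(400) = 0.0038 m-1
bbw = 0.0038 * (400.0 / grid) ** 4.32
with open(os.path.join(OUT, "water_optics.tsv"), "w") as f:
    f.write("# pure seawater absorption aw and backscatter bbw (m-1), 5-nm grid\n")
    f.write("lambda_nm\taw\tbbw\n")
    for l, a, b in zip(grid, aw, bbw):
        f.write(f"{l}\t{a:.6g}\t{b:.6g}\n")

# --- Phytoplankton absorption shape coefficients a0, a1 (Lee-style),
#     normalised so a0(440)=1, a1(440)=0; zero beyond 720 nm.
a0_nodes = {
    400: 0.6843, 410: 0.7782, 420: 0.8637, 430: 0.9603, 440: 1.0000,
    450: 0.9634, 460: 0.9311, 470: 0.8697, 480: 0.7890, 490: 0.7558,
    500: 0.7333, 510: 0.6911, 520: 0.6327, 530: 0.5681, 540: 0.5046,
    550: 0.4262, 560: 0.3433, 570: 0.2950, 580: 0.2784, 590: 0.2595,
    600: 0.2389, 610: 0.2745, 620: 0.3197, 630: 0.3203, 640: 0.3157,
    650: 0.3000, 660: 0.2820, 670: 0.2916, 680: 0.2458, 690: 0.1583,
    700: 0.0973, 710: 0.0528, 720: 0.0300,
}
a1_nodes = {
    400: 0.0205, 410: 0.0129, 420: 0.0060, 430: 0.0020, 440: 0.0000,
    450: 0.0060, 460: 0.0109, 470: 0.0157, 480: 0.0152, 490: 0.0256,
    500: 0.0559, 510: 0.0865, 520: 0.0981, 530: 0.0969, 540: 0.0900,
    550: 0.0781, 560: 0.0659, 570: 0.0600, 580: 0.0581, 590: 0.0540,
    600: 0.0495, 610: 0.0578, 620: 0.0674, 630: 0.0660, 640: 0.0647,
    650: 0.0672, 660: 0.0577, 670: 0.0493, 680: 0.0452, 690: 0.0320,
    700: 0.0172, 710: 0.0093, 720: 0.0053,
}
lam_p = np.array(sorted(a0_nodes))
a0 = np.where(grid <= 720, np.interp(grid, lam_p, [a0_nodes[k] for k in lam_p]), 0.0)
a1 = np.where(grid <= 720, np.interp(grid, lam_p, [a1_nodes[k] for k in lam_p]), 0.0)
with open(os.path.join(OUT, "phyto_shape.tsv"), "w") as f:
    f.write("# phytoplankton absorption shape coefficients (dimensionless), 5-nm grid\n")
    f.write("lambda_nm\ta0\ta1\n")
    for l, x, y in zip(grid, a0, a1):
        f.write(f"{l}\t{x:.6g}\t{y:.6g}\n")

# --- Synthetic benthic endmember library (albedo, dimensionless).
#     Shapes follow the qualitative field description only: bright, slightly
#     red-rising sand; dark flat sediment/rock; vegetation with a green peak,
#     red absorption trough and a red-edge rise.
lam = grid.astype(float)
sand = 0.35 + 0.25 / (1.0 + np.exp(-(lam - 570.0) / 90.0))   # bright, rising
sediment = 0.08 + 0.02 / (1.0 + np.exp(-(lam - 600.0) / 120.0))  # dark, flat-ish
veg = (
    0.03
    + 0.16 * np.exp(-0.5 * ((lam - 555.0) / 30.0) ** 2)       # green peak
    - 0.02 * np.exp(-0.5 * ((lam - 675.0) / 18.0) ** 2)       # chlorophyll trough
    + 0.32 / (1.0 + np.exp(-(lam - 715.0) / 12.0))            # red edge
)
veg = np.clip(veg, 0.01, 1.0)
with open(os.path.join(OUT, "endmembers.tsv"), "w") as f:
    f.write("# synthetic benthic endmember albedo spectra (not measured data)\n")
    f.write("lambda_nm\tsand\talgae\tsediment\n")
    for l, s, v, r in zip(grid, sand, veg, sediment):
        f.write(f"{int(l)}\t{s:.5f}\t{v:.5f}\t{r:.5f}\n")

print("wrote tables to", os.path.abspath(OUT))
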
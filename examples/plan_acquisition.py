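"""Plan an acquisition from the closed-form exclusion-area theory.

For a target reconstruction density Q, the frames needed are
T(a) = Q / (a exp(-aE)); the optimum activation density is a* = 1/E with
T_min = e Q E, where E is the intersection of the algorithm's exclusion
disc (radius r) with the labelled structure.
"""

import smlmkit as sk

Q = 1 / 25  # target: one localization per 5 x 5 nm region
r = 440.0  # exclusion radius of the reference fitter, nm

structures = {
    "0D point (8 x 8 nm)": sk.make_structure("point"),
    "1D strand (8 nm wide)": sk.make_structure("strand"),
    "2D plane": sk.make_structure("plane"),
}

print(f"target density Q = {Q:.3f} /nm^2, exclusion radius r = {r:.0f} nm\n")
t_mins = {}
for name, geom in structures.items():
    e = sk.exclusion_area(geom.exclusion_model(r))
    a_star, t_min = sk.optimal_activation(Q, e)
    t_mins[name] = t_min
    print(f"{name}")
    print(f"  exclusion area E = {e:,.0f} nm^2 = {e / 1e6:.4f} um^2")
    print(f"  optimal activation a* = {a_star * 1e6:.2f} /um^2/frame")
    print(f"  minimum frames T_min = {t_min:,.0f}\n")

names = list(structures)
print("Each added dimension costs roughly an order of magnitude in time:")
print(f"  1D / 0D frame ratio: {t_mins[names[1]] / t_mins[names[0]]:.0f}")
print(f"  2D / 1D frame ratio: {t_mins[names[2]] / t_mins[names[1]]:.0f}")
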
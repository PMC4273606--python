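"""Neuron morphometry: Sholl profiles, spine density, bouton size classes.

Builds parametric neuron skeletons, computes Sholl crossing profiles on
the standard 10/10/300 µm grid, summarises groups, and bins bouton
areas into 3-µm² size classes.
"""

import numpy as np

import rgbtrace as rt

# a straight 300-um neurite crosses each of the 30 circles exactly once
straight = rt.generate_neuron_tree("straight", {"length": 300.0})
profile = rt.sholl(straight, r_start=10, r_step=10, r_end=300)
print("straight neurite crossings:", profile.crossings.tolist())

# a bifurcating tree: crossings double past each branch point
binary = rt.generate_neuron_tree("binary",
                                 {"depth": 3, "segment_length": 60.0})
print("binary tree cable length:", binary.total_cable_length(), "um")
print("binary tree crossings:   ",
      rt.sholl(binary, r_end=250).crossings.tolist())

# group summary across random morphologies (three marker groups)
groups = {name: [rt.sholl(rt.generate_neuron_tree(
    "random", {"max_depth": 5}, rng=seed))
    for seed in range(base, base + 6)]
    for name, base in (("venus", 0), ("mcherry", 10), ("cerulean", 20))}
summary = rt.compare_profiles(groups)
print("\nper-radius group means (first radii):")
print(summary.pivot(index="radius_um", columns="group",
                    values="mean").head(6))

# spine density and bouton size classes
print("\nspine density (15 spines / 10 um):", rt.spine_density(15, 10.0))
areas = np.random.default_rng(10).uniform(0, 12, size=215)
hist = rt.bouton_size_histogram(areas, bin_width=3.0)
print("bouton size classes (percent per 3-um2 bin):")
print(hist.to_string(index=False))
print("\nPercentages sum to 100; bins are half-open [a, a+3).")
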
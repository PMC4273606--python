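"""Expected colour-combination distribution versus transduction rate.

Evaluates the analytic co-transduction model at a few per-vector rates
and prints the single/double/triple-positive fractions among labelled
cells.  Low rates give almost only single-positive cells; at saturation
every cell is triple-positive.
"""

import rgbtrace as rt

for p in (0.05, 0.25, 0.5, 0.75, 1.0):
    f = rt.expected_class_distribution(p, p, p)
    single = f["R"] + f["G"] + f["B"]
    double = f["RG"] + f["GB"] + f["RB"]
    print(f"p={p:4.2f}  single={single:6.3f}  double={double:6.3f}  "
          f"triple={f['RGB']:6.3f}")

# tidy curve table for re-plotting the model overlay
curves = rt.class_curves([i / 100 for i in range(1, 101)])
print("\ncurve table head:")
print(curves.head().to_string(index=False))
print("\nEach row: fraction of labelled cells with 1, 2 or 3 colours at "
      "per-vector rate p; rows sum to 1.")
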
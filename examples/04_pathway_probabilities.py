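"""Upper-tail hypergeometric probabilities for pathway over-representation.

With N = 98 detected metabolites, a cluster of n of them, and a pathway with
m detected members of which k fall inside the cluster, P(X >= k) is the
chance of seeing at least that much overlap if the cluster were a uniform
draw.  These counts are from a published two-group prefrontal-cortex study
(22-metabolite and 18-metabolite control-exclusive clusters).
"""

from netdiff import hypergeometric_tail

cases = [
    ("Arginine and Proline metabolism", 22, 10, 7),
    ("Alanine, Aspartate and Glutamate metabolism", 22, 7, 4),
    ("Butanoate metabolism", 22, 4, 3),
    ("Oxidative phosphorylation", 22, 1, 1),
    ("Purine metabolism (bottom cluster)", 18, 13, 4),
    ("Glycolysis/Gluconeogenesis (bottom cluster)", 18, 1, 1),
]

print(f"{'pathway':<48} {'n':>3} {'m':>3} {'k':>3}  P(X >= k)")
for name, n, m, k in cases:
    p = hypergeometric_tail(98, n, m, k)
    flag = " *" if p < 0.05 else ""
    print(f"{name:<48} {n:>3} {m:>3} {k:>3}  {p:>8.3f}{flag}")
print("* significantly over-represented at the 0.05 level")
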
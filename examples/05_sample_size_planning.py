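"""Plan the sample size of an ICC reliability study.

How many participants are needed so that the 95% CI of an anticipated
ICC(3,1) = 0.75 (two measurement occasions) is no wider than 0.3, with a
50% chance of actually achieving that precision?
"""

from vmhrv import sample_size_icc

n = sample_size_icc(rho0=0.75, width=0.3, conf=0.95, assurance=0.50, k=2)
print(f"anticipated ICC 0.75, CI width <= 0.3 @ 95%, assurance 50%: n = {n}")

for w in (0.2, 0.3, 0.4):
    for rho in (0.6, 0.75, 0.9):
        print(f"  width {w:.1f}, rho0 {rho:.2f} -> n = "
              f"{sample_size_icc(rho, w):d}")

# Precision is cheap when the anticipated ICC is high (the sampling
# variance scales with (1 - rho)^2) and expensive for narrow intervals
# (roughly 1/width^2).
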
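"""Estimate FDS frequency and killer penetrance from ascus class counts.

A cross with a single heteroallelic killer produces two-, three- and
four-spored asci with probabilities (f q^2, 2 f q (1-q), rest), where f is
the first-division-segregation probability of the killer locus and q the
per-spore penetrance of killing.  Three-spored asci are the fingerprint of
incomplete penetrance (q < 1).  The closed-form trinomial MLE recovers
(f, q) from one count vector; here it is run on synthetic counts with known
truth, and on the real count vector of the s x ΔSpok2 cross (80 two-spored
of 197 asci, no three-spored: full penetrance, f ≈ 0.406).
"""

import spoksim as sp

f_true, q_true, N = 0.4, 0.8, 10_000
counts = sp.generate_ascus_counts(f_true, q_true, N, seed=3)
f_hat, q_hat = sp.estimate_fds_penetrance(counts)
print(f"synthetic counts (f={f_true}, q={q_true}, N={N}): "
      f"n2={counts.n2}, n3={counts.n3}, n4={counts.n4}")
print(f"  MLE: f_hat={f_hat:.4f}, q_hat={q_hat:.4f}")

observed = sp.AscusCountData(n2=80, n3=0, n4=117)
f_hat, q_hat = sp.estimate_fds_penetrance(observed)
print(f"\ns x dSpok2 observed counts (80/197 two-spored):")
print(f"  killing percentage: "
      f"{sp.killing_percentage(observed, decimals=1)}%")
print(f"  MLE: f_hat={f_hat:.4f}, q_hat={q_hat:.1f} "
      f"(no three-spored asci -> full penetrance)")
print(f"  implied locus-centromere distance: "
      f"{sp.distance_for_fds(f_hat):.4f} Morgans")
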
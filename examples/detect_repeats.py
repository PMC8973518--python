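"""Detect simple sequence repeats and filter transposable-element hits.

SSR detection follows MISA conventions: perfect tandems of 2-6 bp units
with at least 5 copies; two simple SSRs within 100 bp form a compound SSR.
TE hits (blast tabular format) are filtered at >= 90 % identity and
>= 100 bp, and occupancy is summed over merged alignment spans.
"""

import numpy as np

from marseq import find_ssrs, ssr_class_summary, te_hit_filter
from marseq.synthetic import make_te_hits

rng = np.random.default_rng(5)
background = "".join(rng.choice(list("ACGT"), size=2000))

# plant the silkworm telomeric pentanucleotide and a tetranucleotide
seq = background[:500] + "TTAGG" * 6 + background[500:1000] + "TATT" * 5 + background[1000:]
records = find_ssrs(seq)
for r in records:
    if r.kind == "simple":
        print(f"simple SSR ({r.unit}){r.n_reps} at {r.start}-{r.end}")
    else:
        print(f"compound SSR {r.unit} spanning {r.start}-{r.end} "
              f"(spacers {r.spacers})")

summary = ssr_class_summary(records)
print("\nunit occurrence summary:")
print(summary.to_string(index=False))

hits, n_pass = make_te_hits(seed=5)
kept, per_te = te_hit_filter(hits)
print(f"\nTE hit filtering: {len(kept)}/{len(hits)} hits pass the "
      f">=90% identity / >=100 bp thresholds (expected {n_pass})")
print("occupied bases per TE after merging overlapping spans:")
print(per_te.to_string())
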
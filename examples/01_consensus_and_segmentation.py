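"""Combine per-sample CpG profiles into a class consensus and segment it.

Builds two toy RRBS samples with different sequencing depths, applies the
5-read coverage filter, combines them with depth-reciprocal weights, and
calls hypomethylated regions (>= 3 consecutive CpGs below 0.5).
"""

import pandas as pd

from dremap import combine_profiles, filter_low_coverage, segment
from dremap.consensus import PROFILE_COLUMNS, SampleProfile

rows_a = [("chr1", p, "+", 20, m) for p, m in
          [(100, 18), (150, 2), (200, 1), (250, 3), (300, 19), (350, 17)]]
rows_b = [("chr1", p, "+", 40, m) for p, m in
          [(100, 36), (150, 6), (200, 2), (250, 4), (300, 38), (350, 3)]]

sample_a = SampleProfile("patient_a", 1_000_000,
                         pd.DataFrame(rows_a, columns=PROFILE_COLUMNS))
sample_b = SampleProfile("patient_b", 4_000_000,
                         pd.DataFrame(rows_b, columns=PROFILE_COLUMNS))

combined = combine_profiles([filter_low_coverage(s, 5) for s in [sample_a, sample_b]])
print(combined.sites.round(3).to_string(index=False))
# R is the depth-weighted read count; the deeper sample counts for less per
# read, so equally-informative samples contribute equally to meth.

regions = segment(combined, meth_cutoff=0.5, n_cpg_cutoff=3)
for r in regions:
    print(f"hypomethylated region {r.chrom}:{r.start}-{r.end} "
          f"({r.n_cpg} CpGs, mean methylation {r.mean_meth:.2f})")
# The three consecutive low-methylation CpGs at 150-250 form one candidate
# regulatory element; flanking high-methylation CpGs are excluded.
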
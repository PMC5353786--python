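"""Link regulatory elements to nearest-TSS genes and test expression coupling.

Are gained elements concentrated near genes up-regulated in the cancer
class? Each region is assigned to the gene with the closest transcription
start site; the fraction of gained elements near top-10% up-regulated
genes is compared with the shared-element baseline by a binomial test.
"""

from dremap import (SyntheticConfig, compute_fold_change, dre_gene_enrichment,
                    rank_de_genes)
from dremap.genes import assign_regions
from dremap.pipeline import RunConfig, run
from dremap.synthetic import generate_all

ds = generate_all(SyntheticConfig(seed=42))
res = run(RunConfig(seed=42, stages=("classify",)), "scratch/example_run", dataset=ds)
cm = res.classmap

tss = ds.fixture.annotation.tss_table
fc = compute_fold_change(ds.expression, min_expr=0.1)
measured = set(fc.loc[~fc["excluded"], "gene_id"])
up = rank_de_genes(fc, top_percent=10, direction="up")

gained = assign_regions(cm.gained, tss)
shared = assign_regions(cm.shared, tss)
enr = dre_gene_enrichment(gained, shared, up, measured)

print(f"fraction of gained dREs near top-10% up genes: {enr.fract_R_G:.3f} (n={enr.n_R})")
print(f"same fraction for shared elements:             {enr.fract_S_G:.3f} (n={enr.n_S})")
print(f"enrichment: {enr.enrichment}, binomial p ({enr.direction}): {enr.p_value:.3g}")
# The generator up-regulates genes adjacent to planted gained elements
# (fold 4), so nearly every gained element links to a top-ranked gene while
# shared elements rarely do - a strong, significant enrichment.
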
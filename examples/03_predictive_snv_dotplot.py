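"""Select a compact panel of genotype-predictive SNVs and tabulate a dot plot.

After demultiplexing, a small set of SNVs that discriminate the genotypes
and jointly cover every cell at least 5 times lets assignments be checked
visually: singlet groups show opposite mean allele fractions, doublets
sit in between.
"""

from txdemux import DemuxConfig, SimConfig, demultiplex, simulate_sample
from txdemux.predictive import dotplot_table, greedy_cover, rank_snvs
from txdemux.simulate import draw_genotypes

cfg = SimConfig(n_total=600, n_sites=400, minor_counts=(200,), seed=5)
pair = draw_genotypes(cfg.n_sites, seed=5, config=cfg)
sample = simulate_sample(pair, minor_count=200, ambient_rate=0.1, config=cfg, seed=9)
result = demultiplex(sample.matrix, DemuxConfig(seed=1))

ranked = rank_snvs(sample.matrix, result)
pset = greedy_cover(ranked, sample.matrix, n_cover=5)
print(f"selected {len(pset.site_ids)} SNVs, every cell covered >=5x: {pset.feasible}")

table = dotplot_table(sample.matrix, result, pset)
summary = table.groupby("group")[["cell_fraction", "mean_af"]].mean()
print(summary.round(3))
# mean_af per group: the two singlet genotypes sit near opposite allele
# fractions at the selected sites; doublets average the two.
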
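"""Filter SNVs and export demultiplexer input files.

Applies the minimal SNV filter (mean mAF > 0.999 / < 10 cells covered /
< 5 cells with alt) and writes both the cellSNP-style layout Vireo reads
and the alt/ref matrix pair Souporcell reads.
"""

import tempfile
from pathlib import Path

from txdemux import FilterConfig, SimConfig, export_demux_input, filter_snvs, simulate_sample
from txdemux.simulate import draw_genotypes

cfg = SimConfig(n_total=500, n_sites=400, minor_counts=(100,), seed=5)
pair = draw_genotypes(cfg.n_sites, seed=5, config=cfg)
sample = simulate_sample(pair, minor_count=100, ambient_rate=0.0, config=cfg, seed=9)

filtered = filter_snvs(sample.matrix, FilterConfig())
print(f"filter kept {filtered.n_sites}/{sample.matrix.n_sites} sites")

out = Path(tempfile.mkdtemp())
for dialect in ("vireo", "souporcell"):
    paths = export_demux_input(filtered, dialect, out / dialect)
    print(dialect, "->", ", ".join(p.name for p in paths.values()))
# The vireo layout round-trips losslessly through txdemux.read_counts;
# the souporcell ref matrix equals total - alt elementwise.
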
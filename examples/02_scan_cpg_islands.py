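"""Scan promoter sequences for strong CpG islands.

A strong island is a segment >500 bp with G+C >55% and observed/expected
CpG ratio >0.65; genes carrying one are candidates for methylation-based
regulation.
"""

from methcascade import synthio
from methcascade.cgiscan import annotate_cgi_genes, find_cpg_islands

cfg = synthio.GeneratorConfig(n_genes=20, n_drivers=1, n_passengers=2,
                              n_late_dm=2, cgi_promoter_fraction=0.5, seed=7)
truth = synthio.make_truth(cfg)
promoters = synthio.generate_promoters(cfg, truth)

flags = annotate_cgi_genes(promoters)
print(f"CGI-positive promoters: {sum(flags.values())} of {len(flags)}")

rec = next(p for p in promoters if flags[p.gene_id])
for isl in find_cpg_islands(rec):
    print(f"{rec.gene_id}: island [{isl.start}, {isl.end}) "
          f"length={isl.length} GC={isl.gc_fraction:.2f} "
          f"obs/exp CpG={isl.obs_exp_ratio:.2f}")
# Island coordinates are 0-based half-open offsets within the promoter;
# both composition statistics exceed the calling thresholds.
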
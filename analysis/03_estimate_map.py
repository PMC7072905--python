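#!/usr/bin/env python
"""Estimate the genetic map over the bin markers (selfed-RIL correction
R = 2r/(1+2r), then the configured map function) and tabulate the
per-chromosome characteristics.  Writes map.tsv and map_summary.tsv."""

from pathlib import Path

from rilmap import bincall, datasets, genmap, io
from rilmap.config import PipelineConfig

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
cfg = PipelineConfig.from_yaml(OUT / "config.yaml")

bm = io.read_bins_tsv(OUT / "bins.tsv")
gm = genmap.build_genetic_map(bm, cfg.map_function, cfg.ceiling_cm)
io.write_map_tsv(OUT / "map.tsv", gm)
summary = bincall.binmap_summary(bm, gm)
summary.to_csv(OUT / "map_summary.tsv", sep="\t", index=False)

true_cm = sum(datasets.rice_genetic_lengths_cm().values())
total = summary[summary["chrom"] == "total"].iloc[0]
print(summary.round(2).to_string(index=False))
print(f"\ntotal {total['n_markers']:.0f} markers over "
      f"{total['genetic_length_cm']:.1f} cM ({cfg.map_function}); "
      f"simulated truth {true_cm:.0f} cM "
      f"({100 * (total['genetic_length_cm'] / true_cm - 1):+.1f}%)")
print(f"map -> {OUT / 'map.tsv'}")
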
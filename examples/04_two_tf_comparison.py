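"""Positional relationship between two TFs' binding sites.

Simulates a second TF whose summits sit at signed-exponential offsets
(median 142 bp) from the first TF's summits, then measures nearest-summit
distances and motif enrichment in 50 bp windows.
"""
import tempfile
from pathlib import Path

import numpy as np

import tfdirect as td

out = Path(tempfile.mkdtemp())
cfg = td.SimulationConfig(seed=5, n_genes=600, n_peaks=500, n_chroms=6,
                          chrom_length=700_000)
truth = td.simulate_dataset(cfg, out)

tf_a = td.read_narrowpeak(out / "tfa_rep1.narrowPeak")
tf_b = td.read_narrowpeak(out / "tfb.narrowPeak")

dists, median, dmin, dmax, excluded = td.peak_distance_between_tfs(tf_a, tf_b)
planted = np.median(np.abs(truth.tf_b_offsets))
print(f"nearest-summit distances: n={len(dists)}, "
      f"median={median:.0f} bp (planted {planted:.0f}), "
      f"range {dmin}-{dmax} bp, excluded={excluded}")

genes = td.read_gff3(out / "annotation.gff3")
genome = td.read_fasta(out / "genome.fa")
_, links = td.assign_peaks_to_genes(tf_a, genes)
sites = td.make_binding_sites([l.peak for l in links], genome, width=50,
                              offsets=[l.signed_distance_to_tss for l in links])
bg = td.sample_matched_background(sites, genes, genome, seed=5)
for r in td.motif_enrichment(sites, bg, td.DEFAULT_MOTIF_PANEL):
    flag = "*" if r.significant else "n.s."
    print(f"  {r.motif:<10} {r.observed_fraction:.1%} vs "
          f"{r.background_fraction:.1%}  {flag}")
# A small median distance with a wide range indicates the two TFs bind
# adjacent but distinct sites; the 50 bp windows sharpen motif
# attribution to each TF's own summit.
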
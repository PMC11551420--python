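"""Identify a TF's direct target genes on a synthetic dataset.

Simulates a genome with planted ChIP-Seq peaks and tissue-contrast
expression, then walks the inference chain: reproducible peaks -> bound
genes -> coexpressed genes -> direct targets (bound AND coexpressed).
"""
import tempfile
from pathlib import Path

import pandas as pd

import tfdirect as td
from tfdirect.expression import de_results_to_frame
from tfdirect.synthetic import EMBRYO_GROUPS, SEEDCOAT_GROUPS

out = Path(tempfile.mkdtemp())
cfg = td.SimulationConfig(seed=1, n_genes=200, n_peaks=120, n_chroms=3,
                          noise_fraction=0.1)
truth = td.simulate_dataset(cfg, out)

genes = td.read_gff3(out / "annotation.gff3")
rep1 = td.read_narrowpeak(out / "tfa_rep1.narrowPeak")
rep2 = td.read_narrowpeak(out / "tfa_rep2.narrowPeak")

repro = td.reproducible_peaks(rep1, rep2)
bound, links = td.assign_peaks_to_genes(repro, genes, upstream_window=1000)

groups = pd.read_csv(out / "sample_groups.tsv", sep="\t",
                     index_col=0)["group"].to_dict()
cm = td.CountMatrix.from_tsv(out / "counts.tsv", groups)
tables = [de_results_to_frame(td.nb_exact_test(cm, sc, em))
          for em in EMBRYO_GROUPS for sc in SEEDCOAT_GROUPS]
coexpressed = td.call_coexpressed(tables, min_fold=2, fdr_max=0.01,
                                  min_contrasts=2)
dt = td.call_direct_targets(bound, coexpressed)

print(f"peaks per replicate:     {len(rep1)} / {len(rep2)}")
print(f"reproducible peaks:      {len(repro)}")
print(f"bound genes:             {len(bound)}  (truth {len(truth.bound_genes)})")
print(f"coexpressed genes:       {len(coexpressed)}  "
      f"(truth {len(truth.coexpressed_genes)})")
print(f"direct targets:          {len(dt)}  (truth {len(truth.dt_genes)})")
print(f"recovered truth exactly: {dt == truth.dt_genes}")
# Reproducible peaks drop the replicate-unique noise; the direct-target
# set is the intersection of ChIP-bound genes with genes >= 2-fold up in
# embryo vs seed-coat tissue contrasts (FDR < 0.01, >= 2 of 4 contrasts).
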
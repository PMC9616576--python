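"""Run the full pipeline: simulate, QC, quantify, associate, GWAS, enrichment.

The default scenario plants causal SNPs for several pair-type EV phenotypes
and concentrates 3x the average per-SNP heritability of a complex trait on
those SNPs. The pipeline recovers them via GWAS on rank-transformed EV
abundances, builds flanked SNP sets, and scores heritability enrichment with
a block-jackknife standard error.
"""

import json
import sys
import tempfile

import pandas as pd

from evlink.pipeline import default_config, run_pipeline

outdir = sys.argv[1] if len(sys.argv) > 1 else tempfile.mkdtemp(prefix="evlink_demo_")
config = default_config(outdir, seed=4)
manifest = run_pipeline(config)

print(f"stages run: {', '.join(manifest['stages'])}")
print(f"median GWAS lambda across EV phenotypes: "
      f"{manifest['stages']['gwas']['median_lambda']:.3f} (near 1 = calibrated)")
print("SNP-set sizes:",
      json.dumps(manifest["stages"]["snpsets"]["set_sizes"]))

enr = pd.read_csv(f"{config.outdir}/enrichment.tsv", sep="\t")
print(enr[["annotation", "score", "se"]].to_string(index=False))
print("\nplanted truth concentrates 3x heritability on the EV-causal SNPs, so "
      "scores should sit near 3 within their jackknife standard errors")
print(f"outputs written to {config.outdir}")
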
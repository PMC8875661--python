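"""Decompose adsorption into per-interaction contributions.

Runs the full pipeline on synthetic defaults and prints the
contribution report: mean percentage share of each Abraham term
(eE electron-pair, sS dipolar, aA/bB hydrogen-bonding, vV dispersion/
cavity) in |E_ad|, logK, and logK's entropic/enthalpic and
water/gaseous decompositions.  Dispersion (vV) dominating every column
is the hallmark of physisorption on 2D nanomaterials.
"""

import tempfile

import pandas as pd

from nanosorb.pipeline import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as td:
    config = PipelineConfig(output_dir=td, seed=0, n_compounds=41, repetitions=200)
    artifacts = run_pipeline(config)
    report = pd.read_csv(artifacts["contributions"], index_col=0)

print(report.round(0).astype(int).to_string())
print()
print("The 'sum' row adds the five explicit descriptor terms (intercept "
      "excluded); enthalpic + entropic columns ≈ the direct logK column.")
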
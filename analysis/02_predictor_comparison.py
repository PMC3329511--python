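"""Step 1: brain mass vs body mass as predictors of time to weaning."""

from pathlib import Path

from weantime import read_trait_table, step1_compare_predictors

ROOT = Path(__file__).resolve().parent.parent / "results"

table = read_trait_table(ROOT / "dataset" / "traits.csv")
report = step1_compare_predictors(table)

out = ROOT / "steps"
out.mkdir(parents=True, exist_ok=True)
(out / "step1_compare_predictors.json").write_text(report.to_json())
print(report.narrative)
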
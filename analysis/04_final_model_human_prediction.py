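"""Step 4: full ANCOVA, variance partition, leave-humans-out prediction."""

from pathlib import Path

from weantime import read_trait_table, step4_final_model

ROOT = Path(__file__).resolve().parent.parent / "results"

table = read_trait_table(ROOT / "dataset" / "traits.csv")
report = step4_final_model(table)

out = ROOT / "steps"
out.mkdir(parents=True, exist_ok=True)
(out / "step4_final_model.json").write_text(report.to_json())
print(report.narrative)
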
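"""Steps 2-3: limb-biomechanics grade shift and the dietary-profile effect."""

from pathlib import Path

from weantime import read_trait_table, step2_grade_shift, step3_diet_effect

ROOT = Path(__file__).resolve().parent.parent / "results"

table = read_trait_table(ROOT / "dataset" / "traits.csv")
out = ROOT / "steps"
out.mkdir(parents=True, exist_ok=True)
for step in (step2_grade_shift, step3_diet_effect):
    report = step(table)
    (out / f"{report.step}.json").write_text(report.to_json())
    print(report.narrative)
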
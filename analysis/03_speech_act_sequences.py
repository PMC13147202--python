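"""Speech-act proportions, diversity, and a-priori sequence statistics.

Writes per-transcript sequence counts/opportunities/rates for both tasks to
results/sequences_<task>.tsv. The conversation table should show the
planted structure: backchannel rates near 0.35 for non-autistic groups vs
0.15 for autistic groups, and higher self-elaboration rates for females.
"""

from pathlib import Path

import pandas as pd

from pragmalang.sequences import (
    count_conversation_sequences,
    count_narrative_sequences,
    speech_act_diversity,
    speech_act_proportions,
)
from pragmalang.transcripts import read_transcript

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for task in ("narrative", "conversation"):
        files = sorted((ROOT / "cohorts" / task).glob("*.txt"))
        if not files:
            raise SystemExit("run analysis/01_simulate_cohorts.py first")
        rows = []
        for path in files:
            t = read_transcript(path)
            prof = (
                count_narrative_sequences(t)
                if task == "narrative"
                else count_conversation_sequences(t)
            )
            row = {"id": t.id, "diagnosis": t.diagnosis, "sex": t.sex,
                   "viq": t.covariates.get("viq")}
            for name in prof.counts:
                row[f"{name}_count"] = prof.counts[name]
                row[f"{name}_rate"] = prof.rates[name]
            if task == "narrative":
                row["diversity"] = speech_act_diversity(t)
                props = speech_act_proportions(t)
                row["statement_pct"] = props["statement"]
            rows.append(row)
        table = pd.DataFrame(rows)
        out = ROOT / f"sequences_{task}.tsv"
        table.to_csv(out, sep="\t", index=False)
        rate_cols = [c for c in table.columns if c.endswith("_rate")]
        print(f"\n{task}: {len(table)} transcripts -> {out}")
        print(table.groupby(["diagnosis", "sex"])[rate_cols].mean().round(3).to_string())


if __name__ == "__main__":
    main()
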
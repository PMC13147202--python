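"""Generate the synthetic study cohorts.

Writes one narrative and one conversation cohort at the emulated study's
group sizes (73 autistic males, 27 autistic females, 40 non-autistic males,
47 non-autistic females) to results/cohorts/, plus a truth table of the
planted generator parameters that later steps can be checked against.
"""

import sys
from pathlib import Path

import pandas as pd

from pragmalang.simulate import (
    GROUPS,
    STUDY_GROUP_SIZES,
    default_config,
    generate_cohort,
    true_kl,
)
from pragmalang.transcripts import Task, save_transcript

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42
OUT = Path(__file__).resolve().parents[1] / "results" / "cohorts"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth_rows = []
    for task in (Task.NARRATIVE, Task.CONVERSATION):
        cfg = default_config(task, n_per_group=STUDY_GROUP_SIZES, seed=SEED)
        cohort = generate_cohort(cfg, task)
        task_dir = OUT / task.value
        task_dir.mkdir(exist_ok=True)
        for t in cohort:
            save_transcript(t, task_dir / f"{t.id}.txt")
        print(f"{task.value}: wrote {len(cohort)} transcripts to {task_dir}")
        for i, a in enumerate(GROUPS):
            for b in GROUPS[i + 1 :]:
                f, r, s = true_kl(cfg.groups[a], cfg.groups[b])
                truth_rows.append(
                    {
                        "task": task.value,
                        "group_a": "/".join(a),
                        "group_b": "/".join(b),
                        "true_kl_symmetric": s,
                    }
                )
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(OUT / "planted_kl_truth.tsv", sep="\t", index=False)
    print("\nPlanted chain divergences (nats/step):")
    print(truth.to_string(index=False, float_format=lambda x: f"{x:.4f}"))


if __name__ == "__main__":
    main()
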
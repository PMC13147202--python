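"""Word-category profiles per transcript.

Reads the cohorts from step 01, applies the example lexicon, and writes
per-transcript counts and percent-of-word-count for every category and
composite to results/word_profiles_<task>.tsv, plus a group-mean summary.
The expectation under the generator: complex-affect percent around 2% for
female groups and 1% for male groups, other categories equal across groups.
"""

from pathlib import Path

from pragmalang.lexicon import cohort_profiles, load_example_lexicon
from pragmalang.transcripts import read_transcript

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    lex = load_example_lexicon()
    for task in ("narrative", "conversation"):
        files = sorted((ROOT / "cohorts" / task).glob("*.txt"))
        if not files:
            raise SystemExit("run analysis/01_simulate_cohorts.py first")
        transcripts = [read_transcript(p) for p in files]
        table = cohort_profiles(transcripts, lex)
        out = ROOT / f"word_profiles_{task}.tsv"
        table.to_csv(out, sep="\t", index=False)
        summary = (
            table.groupby(["diagnosis", "sex"])[
                ["word_count", "ComplexAffectiveStates_pct", "AffectAndCognition_pct"]
            ]
            .mean()
            .round(2)
        )
        print(f"\n{task}: {len(table)} profiles -> {out}")
        print(summary.to_string())


if __name__ == "__main__":
    main()
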
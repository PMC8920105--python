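"""Compute per-patient anticoagulation-quality indices for the cohort.

Reads results/cohort/, computes WSI, Rosendaal TTR with NICE class,
log-INR variability, WCM and predicted liver weight, writes
results/indices.tsv, and prints cohort-level summaries.
"""

from pathlib import Path

from warfarin_pkpd import compute_indices, read_cohort

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort_dir = BASE / "cohort"
    patients = read_cohort(cohort_dir / "visits.tsv", cohort_dir / "demographics.tsv")
    indices = compute_indices(patients)
    indices.to_csv(BASE / "indices.tsv", sep="\t", index=False, float_format="%.6f")

    good = (indices["ttr_class"] == "good").mean()
    print(f"indices for {len(indices)} patients -> {BASE / 'indices.tsv'}")
    print(f"good anticoagulation control (TTR >= 65%): {100 * good:.1f}% of cohort")
    print("cohort means:")
    print(
        indices[["wsi", "ttr", "log_inr_var", "wcm", "liver_weight"]]
        .mean()
        .round(3)
        .to_string()
    )


if __name__ == "__main__":
    main()
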
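"""Simulate the default 220-patient warfarin cohort.

Draws demographics and true PK parameters from the study population
distributions, titrates each patient's dose to a drawn target INR with
the steady-state model, and writes the visit, demographics and truth
tables under results/cohort/.
"""

from pathlib import Path

from warfarin_pkpd import GeneratorConfig, generate_cohort, write_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20260901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = GeneratorConfig(seed=SEED)
    patients, truth = generate_cohort(cfg)
    write_cohort(patients, OUT / "visits.tsv", OUT / "demographics.tsv")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False, float_format="%.6f")
    n_visits = sum(len(p.visits) for p in patients)
    print(f"simulated {len(patients)} patients, {n_visits} visits -> {OUT}")
    print("true parameter means:")
    print(truth[["c_max", "k", "cl", "v_d"]].mean().round(3).to_string())


if __name__ == "__main__":
    main()
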
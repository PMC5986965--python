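"""Stage classification by linear SVM with participant-wise LOOCV.

Compares the pooled-fit protocol (feature chain fitted once on the full
cohort — optimistic, as the held-out participant informs selection)
against the nested protocol (chain refit inside every training fold),
with default and Bayesian-optimized hyperparameters.  Writes the metric
table and the per-fold reports under results/.
"""

import json

import pandas as pd

from common import RESULTS, STUDY, study_cohort
from fcstage.classify import SvmHyperparams, bayes_optimize, loocv_by_participant


def main() -> None:
    x_pre, x_post, participants, _ = study_cohort()

    rows = []
    reports = {}
    for mode in ("pooled", "nested"):
        report = loocv_by_participant(x_pre, x_post, participants, mode=mode)
        reports[f"{mode}_default"] = report
        rows.append({"protocol": mode, "hyperparams": "default",
                     "accuracy": report.accuracy, "sensitivity": report.sensitivity,
                     "specificity": report.specificity, "auc": report.auc})

    hp, trace = bayes_optimize(
        x_pre, x_post, participants, n_iter=30, rng_seed=STUDY.rng_seed,
        mode="pooled",
    )
    report = loocv_by_participant(x_pre, x_post, participants, hp=hp)
    reports["pooled_optimized"] = report
    rows.append({"protocol": "pooled",
                 "hyperparams": f"optimized (C={hp.cost:.3g}, scale={hp.kernel_scale:.3g})",
                 "accuracy": report.accuracy, "sensitivity": report.sensitivity,
                 "specificity": report.specificity, "auc": report.auc})

    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "cv_summary.tsv", sep="\t", index=False, float_format="%.4f")
    print(table.to_string(index=False))
    print(f"\nBayesian optimization: {len(trace)} evaluations, "
          f"best CV error {min(e for _, e in trace):.3f}")

    for name, rep in reports.items():
        (RESULTS / f"cv_{name}.json").write_text(json.dumps(rep.to_dict(), indent=1))
    print(f"per-fold reports -> {RESULTS}/cv_*.json")


if __name__ == "__main__":
    main()
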
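"""Cohort-level pre/post analysis: the model/results pair.

:class:`CohortAnalysis` is built from a :class:`~gripscore.simulate.CohortDataset`
(simulated or loaded from disk) and its :meth:`~CohortAnalysis.fit` runs the
whole analysis in a fixed order:

1. score every visit (already done at dataset construction) and classify each
   patient as functional/nonfunctional from the 3-month post-operative ODI;
2. pool all (subject, visit) pairs carrying both a tracking MAE and an ODI
   and correlate them (MAE as a 0–1 fraction);
3. screen the MAE~ODI regression with the leave-one-out Cook's distance and
   the 4/(n−2) rule, then re-correlate without the flagged points;
4. Bland–Altman agreement between the two measures (direction MAE − ODI);
5. per-subject percent improvement between first and last analysed visits and
   Welch t-tests of each patient subgroup against the controls;
6. correlation of the percent improvements of the two measures across
   patients, with and without subjects owning a flagged point.

The result object carries every statistic, renders a text ``summary()`` and
serialises to a nested report dict.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import InvalidParameterError
from .simulate import CohortDataset
from .stats import (
    AgreementResult,
    CorrelationResult,
    GroupComparison,
    PairedScores,
    RegressionDiagnostics,
    bland_altman,
    fit_simple_regression,
    improvement_magnitude,
    pearson,
    welch_t_test,
)
from .surveys import FunctionalStatus, classify_functional, odi_index

__all__ = ["CohortAnalysis", "CohortResults", "GroupScore", "analyze_cohort"]


@dataclass(frozen=True)
class GroupScore:
    """Mean ± SD of the visit MAE for one group at one timepoint."""

    label: str
    mean: float
    sd: float
    n: int


@dataclass(frozen=True, eq=False)
class CohortResults:
    """Everything the cohort analysis computes.

    Attributes mirror the published-table structure: ``group_scores`` is the
    score summary (control first/last, patient pre/post split by functional
    status), ``improvements`` the percent-improvement contrasts with t-tests
    against controls, and the correlation/agreement blocks compare the
    tracking score with the disability index.
    """

    group_scores: tuple[GroupScore, ...]
    functional_status: dict[str, str]
    improvements: dict[str, dict]
    paired: Optional[PairedScores]
    correlation_all: Optional[CorrelationResult]
    regression: Optional[RegressionDiagnostics]
    outlier_subjects: tuple[tuple[str, str], ...]
    correlation_screened: Optional[CorrelationResult]
    agreement: Optional[AgreementResult]
    improvement_correlation: Optional[CorrelationResult]
    improvement_correlation_screened: Optional[CorrelationResult]
    n_control: int
    n_patient: int

    def group_score(self, label: str) -> Optional[GroupScore]:
        for g in self.group_scores:
            if g.label == label:
                return g
        return None

    def summary(self) -> str:
        """Human-readable summary table, two-decimal rendering."""
        lines = []
        lines.append("Cohort tracking-score analysis")
        lines.append("=" * 62)
        lines.append(f"{'Group / timepoint':<40}{'MAE mean±SD (n)':>22}")
        lines.append("-" * 62)
        for g in self.group_scores:
            lines.append(f"{g.label:<40}{g.mean:>8.2f} ± {g.sd:<5.2f} ({g.n})")
        lines.append("-" * 62)
        lines.append("% improvement (positive = error decreased)")
        for label, rec in self.improvements.items():
            mean, sd = rec["mean"], rec["sd"]
            p = rec.get("p_vs_control")
            tail = f"  p vs control = {p:.3g}" if p is not None else ""
            lines.append(f"  {label:<30}{100 * mean:>7.0f}% ± {100 * sd:.0f}%{tail}")
        if self.correlation_all is not None:
            lines.append("-" * 62)
            c = self.correlation_all
            lines.append(f"MAE vs ODI (pooled, n={c.n}): r = {c.r:.3f}, p = {c.p_value:.3g}")
            if self.outlier_subjects:
                flagged = ", ".join(f"{s}/{v}" for s, v in self.outlier_subjects)
                lines.append(f"Cook's-distance outliers (d >= 4/(n-2)): {flagged}")
            if self.correlation_screened is not None:
                c2 = self.correlation_screened
                lines.append(
                    f"MAE vs ODI (outliers removed, n={c2.n}): "
                    f"r = {c2.r:.3f}, p = {c2.p_value:.3g}"
                )
            if self.agreement is not None:
                a = self.agreement
                lines.append(
                    f"Bland-Altman (MAE - ODI): bias {a.bias:.2f} "
                    f"[95% CI {a.bias_ci[0]:.2f}, {a.bias_ci[1]:.2f}], "
                    f"LoA [{a.loa_lower:.2f}, {a.loa_upper:.2f}]"
                )
        if self.improvement_correlation is not None:
            c = self.improvement_correlation
            lines.append(
                f"% improvement MAE vs ODI (n={c.n}): r = {c.r:.3f}, p = {c.p_value:.3g}"
            )
        return "\n".join(lines)

    def to_report(self) -> dict:
        """Nested, JSON-serialisable report of every computed statistic."""

        def corr(c: Optional[CorrelationResult]):
            if c is None:
                return None
            return {"r": c.r, "p_value": c.p_value, "n": c.n}

        report = {
            "schema_version": "1.0",
            "n_control": self.n_control,
            "n_patient": self.n_patient,
            "group_scores": [
                {"label": g.label, "mean": g.mean, "sd": g.sd, "n": g.n}
                for g in self.group_scores
            ],
            "functional_status": dict(self.functional_status),
            "improvements": {
                label: {
                    "mean": rec["mean"],
                    "sd": rec["sd"],
                    "n": rec["n"],
                    "p_vs_control": rec.get("p_vs_control"),
                }
                for label, rec in self.improvements.items()
            },
            "correlation": {
                "all": corr(self.correlation_all),
                "outliers": [list(t) for t in self.outlier_subjects],
                "screened": corr(self.correlation_screened),
            },
            "agreement": None,
            "improvement_correlation": {
                "all": corr(self.improvement_correlation),
                "screened": corr(self.improvement_correlation_screened),
            },
        }
        if self.agreement is not None:
            a = self.agreement
            report["agreement"] = {
                "bias": a.bias,
                "bias_ci": list(a.bias_ci),
                "loa_lower": a.loa_lower,
                "loa_upper": a.loa_upper,
                "sd_diff": a.sd_diff,
                "n": a.n,
                "direction": a.direction,
            }
        return report


class CohortAnalysis:
    """The analysis model: build from a cohort, ``fit()`` to get results.

    Parameters
    ----------
    dataset : CohortDataset
        Scored visits, surveys and group labels.
    t_test_variant : {"welch", "pooled"}
        Two-sample test used for group contrasts.
    bias_ci_method : {"normal", "t"}
        Multiplier for the Bland–Altman bias confidence interval.
    outlier_passes : int
        Number of Cook's-distance screening passes (the published analysis
        uses a single pass).
    """

    def __init__(
        self,
        dataset: CohortDataset,
        t_test_variant: str = "welch",
        bias_ci_method: str = "normal",
        outlier_passes: int = 1,
    ) -> None:
        if outlier_passes < 0:
            raise InvalidParameterError("outlier_passes must be >= 0")
        self.dataset = dataset
        self.t_test_variant = t_test_variant
        self.bias_ci_method = bias_ci_method
        self.outlier_passes = outlier_passes

    # -- helpers ---------------------------------------------------------

    def _first_last_visits(self, subject_id: str):
        visits = self.dataset.visits_of(subject_id)
        if not visits:
            return None, None
        return visits[0], visits[-1]

    def _groups(self):
        controls = [s for s in self.dataset.subjects if s.group == "control"]
        patients = [s for s in self.dataset.subjects if s.group == "patient"]
        return controls, patients

    def _odi_value(self, subject_id: str, visit_id: str) -> Optional[float]:
        resp = self.dataset.odi_of(subject_id, visit_id)
        if resp is None:
            return None
        return odi_index(resp).value

    # -- fitting ---------------------------------------------------------

    def fit(self) -> CohortResults:
        ds = self.dataset
        controls, patients = self._groups()

        # classify each patient from the last visit's ODI (3-month post-op)
        status: dict[str, str] = {}
        for s in patients:
            first, last = self._first_last_visits(s.subject_id)
            post_odi = self._odi_value(s.subject_id, last.visit_id) if last else None
            if post_odi is not None:
                status[s.subject_id] = classify_functional(post_odi).value

        def mae_at(subjects, picker) -> list[float]:
            vals = []
            for s in subjects:
                first, last = self._first_last_visits(s.subject_id)
                v = picker(first, last)
                if v is not None:
                    vals.append(v.visit_mae)
            return vals

        control_first = mae_at(controls, lambda f, l: f)
        control_last = mae_at(controls, lambda f, l: l)
        patient_pre = mae_at(patients, lambda f, l: f)
        patient_post = mae_at(patients, lambda f, l: l)
        func_ids = {sid for sid, st in status.items() if st == FunctionalStatus.FUNCTIONAL.value}
        nonfunc_ids = {
            sid for sid, st in status.items() if st == FunctionalStatus.NONFUNCTIONAL.value
        }
        post_func = mae_at(
            [s for s in patients if s.subject_id in func_ids], lambda f, l: l
        )
        post_nonfunc = mae_at(
            [s for s in patients if s.subject_id in nonfunc_ids], lambda f, l: l
        )

        def gs(label, vals) -> Optional[GroupScore]:
            if not vals:
                return None
            arr = np.asarray(vals, dtype=float)
            sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            return GroupScore(label, float(arr.mean()), sd, int(arr.size))

        group_scores = tuple(
            g
            for g in (
                gs("control_first", control_first),
                gs("control_last", control_last),
                gs("patient_pre", patient_pre),
                gs("patient_post", patient_post),
                gs("patient_post_functional", post_func),
                gs("patient_post_nonfunctional", post_nonfunc),
            )
            if g is not None
        )

        # per-subject percent improvement (magnitude: positive = error down)
        def improvements_of(subjects) -> dict[str, float]:
            out = {}
            for s in subjects:
                first, last = self._first_last_visits(s.subject_id)
                if first is not None and last is not None and first is not last:
                    out[s.subject_id] = improvement_magnitude(first.visit_mae, last.visit_mae)
            return out

        imp_control = improvements_of(controls)
        imp_patient = improvements_of(patients)
        imp_func = {k: v for k, v in imp_patient.items() if k in func_ids}
        imp_nonfunc = {k: v for k, v in imp_patient.items() if k in nonfunc_ids}

        improvements: dict[str, dict] = {}
        ctrl_vals = list(imp_control.values())

        def imp_entry(label, values, vs_control: bool):
            if not values:
                return
            arr = np.asarray(values, dtype=float)
            rec = {
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                "n": int(arr.size),
            }
            if vs_control and len(ctrl_vals) >= 2 and arr.size >= 2:
                cmp = welch_t_test(arr, np.asarray(ctrl_vals), variant=self.t_test_variant)
                rec["p_vs_control"] = cmp.p_value
                rec["t_vs_control"] = cmp.t_statistic
            improvements[label] = rec

        imp_entry("control", ctrl_vals, vs_control=False)
        imp_entry("patient", list(imp_patient.values()), vs_control=True)
        imp_entry("patient_functional", list(imp_func.values()), vs_control=True)
        imp_entry("patient_nonfunctional", list(imp_nonfunc.values()), vs_control=True)

        # pooled pairs with both measures, MAE on the 0-1 fraction scale
        ids, fracs, odis = [], [], []
        for v in ds.visits:
            o = self._odi_value(v.subject_id, v.visit_id)
            if o is not None:
                ids.append((v.subject_id, v.visit_id))
                fracs.append(min(v.visit_mae / 100.0, 1.0))
                odis.append(o)
        paired = None
        correlation_all = None
        regression = None
        correlation_screened = None
        agreement = None
        outlier_subjects: tuple[tuple[str, str], ...] = ()
        if len(ids) >= 4:
            paired = PairedScores(
                subject_ids=tuple(f"{s}/{v}" for s, v in ids),
                mae_fraction=np.asarray(fracs),
                odi=np.asarray(odis),
            )
            degenerate = np.ptp(paired.odi) == 0 or np.ptp(paired.mae_fraction) == 0
            keep = np.ones(len(ids), dtype=bool)
            if not degenerate:
                correlation_all = pearson(paired.odi, paired.mae_fraction)
                for _ in range(self.outlier_passes):
                    regression = fit_simple_regression(
                        paired.odi[keep], paired.mae_fraction[keep]
                    )
                    if not regression.outlier_flags.any():
                        break
                    kept_idx = np.flatnonzero(keep)
                    keep[kept_idx[regression.outlier_flags]] = False
                if self.outlier_passes == 0:
                    regression = fit_simple_regression(paired.odi, paired.mae_fraction)
                outlier_subjects = tuple(ids[i] for i in np.flatnonzero(~keep))
                if (~keep).any() and keep.sum() >= 3 and (
                    np.ptp(paired.odi[keep]) > 0
                    and np.ptp(paired.mae_fraction[keep]) > 0
                ):
                    correlation_screened = pearson(
                        paired.odi[keep], paired.mae_fraction[keep]
                    )
            agreement = bland_altman(
                paired.mae_fraction, paired.odi, ci_method=self.bias_ci_method
            )

        # improvement-vs-improvement correlation across patients
        improvement_correlation = None
        improvement_correlation_screened = None
        flagged_subjects = {s for s, _ in outlier_subjects}
        imp_pairs = []
        for s in patients:
            first, last = self._first_last_visits(s.subject_id)
            if first is None or last is None or first is last:
                continue
            o_pre = self._odi_value(s.subject_id, first.visit_id)
            o_post = self._odi_value(s.subject_id, last.visit_id)
            if o_pre in (None, 0) or o_post is None:
                continue
            imp_pairs.append(
                (
                    s.subject_id,
                    improvement_magnitude(first.visit_mae, last.visit_mae),
                    improvement_magnitude(o_pre, o_post),
                )
            )
        if len(imp_pairs) >= 3:
            m = np.asarray([p[1] for p in imp_pairs])
            o = np.asarray([p[2] for p in imp_pairs])
            if np.ptp(m) > 0 and np.ptp(o) > 0:
                improvement_correlation = pearson(o, m)
            kept = [p for p in imp_pairs if p[0] not in flagged_subjects]
            if flagged_subjects and len(kept) >= 3:
                m2 = np.asarray([p[1] for p in kept])
                o2 = np.asarray([p[2] for p in kept])
                if np.ptp(m2) > 0 and np.ptp(o2) > 0:
                    improvement_correlation_screened = pearson(o2, m2)

        return CohortResults(
            group_scores=group_scores,
            functional_status=status,
            improvements=improvements,
            paired=paired,
            correlation_all=correlation_all,
            regression=regression,
            outlier_subjects=outlier_subjects,
            correlation_screened=correlation_screened,
            agreement=agreement,
            improvement_correlation=improvement_correlation,
            improvement_correlation_screened=improvement_correlation_screened,
            n_control=len(controls),
            n_patient=len(patients),
        )


def analyze_cohort(dataset: CohortDataset, **kwargs) -> CohortResults:
    """Run the full cohort analysis; functional wrapper around the model."""
    return CohortAnalysis(dataset, **kwargs).fit()
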
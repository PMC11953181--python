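"""Agreement and diagnostic metrics with the reporting layout of a
method-comparison study.

Segmentation overlap is scored with the Dice similarity coefficient,
continuous DSA agreement with the two-way random-effects,
absolute-agreement, single-measure intraclass correlation ICC(2,1),
and stenosis classification with accuracy / sensitivity / specificity
plus exact Clopper-Pearson 95% binomial intervals (stenosis is the
positive class).  Reports are stratified overall / per modality /
severe-threshold, at slice granularity and, via the narrowest-slice
rule, at disc-level granularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from statsmodels.stats.proportion import proportion_confint

from .stenosis import (
    SLICES_PER_LEVEL,
    classify_dichotomous,
    classify_severe,
)


# ---------------------------------------------------------------------------
# primitive metrics


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A&B| / (|A|+|B|); both-empty -> 1."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def icc(pairs: np.ndarray) -> tuple[float, tuple[float, float]]:
    """ICC(2,1) absolute agreement with its F-based 95% CI.

    ``pairs`` is (n_subjects, 2): the same quantity measured by two
    raters/methods per subject.  Degenerate input (no between-subject
    variance) is signalled explicitly rather than returning NaN quietly.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need an (n >= 3, 2) array of paired measurements")
    if not np.all(np.isfinite(pairs)):
        raise ValueError("paired measurements must be finite")
    if np.allclose(pairs.var(axis=0).sum(), 0.0):
        raise ValueError("zero variance across subjects: ICC undefined")
    n = pairs.shape[0]
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), 2),
        "rater": np.tile([0, 1], n),
        "score": pairs.ravel(),
    })
    res = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    # two-way random effects, absolute agreement, single measure
    mask = res["Type"].isin(("ICC2", "ICC(A,1)"))
    row = res[mask].iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = row[ci_col]
    return float(row["ICC"]), (float(lo), float(hi))


@dataclass(frozen=True)
class ConfusionCounts:
    """Stenosis = positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _proportion(k: int, n: int) -> dict:
    if n == 0:
        return {"percent": math.nan, "ci": (math.nan, math.nan), "k": k, "n": n}
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")  # Clopper-Pearson
    return {"percent": 100.0 * k / n, "ci": (100.0 * lo, 100.0 * hi), "k": k, "n": n}


def confusion_metrics(counts: ConfusionCounts) -> dict[str, dict]:
    """Accuracy, sensitivity, specificity as percentages with exact
    (Clopper-Pearson) 95% CIs; zero-denominator metrics come back as
    NaN rather than raising."""
    return {
        "accuracy": _proportion(counts.tp + counts.tn, counts.total),
        "sensitivity": _proportion(counts.tp, counts.tp + counts.fn),
        "specificity": _proportion(counts.tn, counts.tn + counts.fp),
        "ci_method": "Clopper-Pearson",
    }


def narrowest_slice_comparison(
    algorithm_dsas: dict, reader_dsa: dict, tolerance_mm2: float = 1.0
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Compare per-level algorithmic minima with a reader's chosen slice.

    ``algorithm_dsas`` maps a level key to its per-slice DSA sequence;
    ``reader_dsa`` maps the same keys to the reader's DSA at the slice
    they judged narrowest.  Per level: |difference| <= tolerance ->
    ``equal``; algorithm minimum smaller -> ``algorithm_narrower``
    (algorithm found a narrower slice than the reader); larger ->
    ``reader_narrower``.  Levels missing a reader value are skipped and
    reported.
    """
    rows = []
    skipped = 0
    for key, slice_dsas in algorithm_dsas.items():
        if key not in reader_dsa:
            skipped += 1
            continue
        alg_min = float(np.min(slice_dsas))
        rd = float(reader_dsa[key])
        if abs(alg_min - rd) <= tolerance_mm2:
            cat = "equal"
        elif alg_min < rd:
            cat = "algorithm_narrower"
        else:
            cat = "reader_narrower"
        rows.append({"level_key": key, "algorithm_min": alg_min, "reader": rd, "category": cat})
    frame = pd.DataFrame(rows, columns=["level_key", "algorithm_min", "reader", "category"])
    counts = {c: int((frame["category"] == c).sum())
              for c in ("equal", "algorithm_narrower", "reader_narrower")}
    counts["total"] = len(frame)
    counts["skipped"] = skipped
    return frame, counts


# ---------------------------------------------------------------------------
# test-set evaluation


@dataclass
class EvalReport:
    """Tables 2/3-shaped report: per-stratum segmentation agreement and
    classification performance."""

    segmentation: pd.DataFrame   # stratum, dsc_mean, dsc_sd, icc, icc_lo, icc_hi, n_slices
    classification: pd.DataFrame  # stratum, metric percentages + CIs + raw counts
    slice_table: pd.DataFrame    # per-slice dsa_pred, dsa_true, dice
    level_table: pd.DataFrame    # per-level minima and calls
    ci_method: str = "Clopper-Pearson"
    notes: list[str] = field(default_factory=list)

    def render(self) -> str:
        """Plain-text rendering mirroring the published table layout."""
        out = ["Segmentation performance (DSC, ICC)"]
        for _, r in self.segmentation.iterrows():
            icc_txt = ("n/a" if not np.isfinite(r.icc)
                       else f"{r.icc:.2f} ({r.icc_lo:.2f}-{r.icc_hi:.2f})")
            out.append(f"  {r.stratum:<12} DSC {r.dsc_mean:.2f} +/- {r.dsc_sd:.2f}   "
                       f"ICC {icc_txt}   n={int(r.n_slices)}")
        out.append(f"Stenosis classification ({self.ci_method} 95% CI)")
        for _, r in self.classification.iterrows():
            def cell(m):
                if not np.isfinite(r[f"{m}_pct"]):
                    return f"{m} n/a"
                return (f"{m} {r[f'{m}_pct']:.1f} [{int(r[f'{m}_k'])}/{int(r[f'{m}_n'])}] "
                        f"({r[f'{m}_lo']:.1f}-{r[f'{m}_hi']:.1f})")
            out.append(f"  {r.stratum:<16} " + "  ".join(cell(m) for m in
                                                         ("accuracy", "sensitivity", "specificity")))
        for n in self.notes:
            out.append(f"  note: {n}")
        return "\n".join(out)


def _confusion_from_calls(truth_pos: np.ndarray, pred_pos: np.ndarray) -> ConfusionCounts:
    truth_pos = np.asarray(truth_pos, bool)
    pred_pos = np.asarray(pred_pos, bool)
    return ConfusionCounts(
        tp=int((truth_pos & pred_pos).sum()),
        fp=int((~truth_pos & pred_pos).sum()),
        tn=int((~truth_pos & ~pred_pos).sum()),
        fn=int((truth_pos & ~pred_pos).sum()),
    )


def _classification_row(stratum: str, truth_pos, pred_pos) -> dict:
    m = confusion_metrics(_confusion_from_calls(truth_pos, pred_pos))
    row = {"stratum": stratum}
    for name in ("accuracy", "sensitivity", "specificity"):
        d = m[name]
        row[f"{name}_pct"] = round(d["percent"], 1) if np.isfinite(d["percent"]) else math.nan
        row[f"{name}_lo"], row[f"{name}_hi"] = (round(v, 1) for v in d["ci"])
        row[f"{name}_k"], row[f"{name}_n"] = d["k"], d["n"]
    return row


def evaluate_testset(slice_table: pd.DataFrame) -> EvalReport:
    """Build the full report from a per-slice results table.

    ``slice_table`` needs one row per test slice with columns
    ``patient_id, mode, level, offset_mm, dsa_pred, dsa_true, dice``.
    Slice-level metrics run over all slices; level metrics apply the
    narrowest-slice rule within each (patient, mode, level) group of 11.
    """
    required = {"patient_id", "mode", "level", "offset_mm", "dsa_pred", "dsa_true", "dice"}
    missing = required - set(slice_table.columns)
    if missing:
        raise ValueError(f"slice table lacks columns {sorted(missing)}")
    bad = slice_table.groupby(["patient_id", "mode", "level"]).size()
    bad = bad[bad != SLICES_PER_LEVEL]
    if len(bad):
        raise ValueError(f"levels without exactly {SLICES_PER_LEVEL} slices: {bad.index.tolist()}")

    strata = {"Overall CT": slice_table}
    for mode, sub in slice_table.groupby("mode"):
        strata[f"{mode.capitalize()} CT"] = sub

    seg_rows, cls_rows = [], []
    for name, sub in strata.items():
        try:
            icc_val, (lo, hi) = icc(np.column_stack([sub.dsa_true, sub.dsa_pred]))
        except ValueError:
            icc_val, lo, hi = math.nan, math.nan, math.nan
        seg_rows.append({
            "stratum": name,
            "dsc_mean": round(float(sub.dice.mean()), 2),
            "dsc_sd": round(float(sub.dice.std(ddof=1)), 2),
            "icc": round(icc_val, 2) if np.isfinite(icc_val) else icc_val,
            "icc_lo": round(lo, 2) if np.isfinite(lo) else lo,
            "icc_hi": round(hi, 2) if np.isfinite(hi) else hi,
            "n_slices": len(sub),
        })
        cls_rows.append(_classification_row(
            name,
            truth_pos=sub.dsa_true < 100.0,
            pred_pos=sub.dsa_pred < 100.0,
        ))
    cls_rows.append(_classification_row(
        "Severe stenosis CT",
        truth_pos=slice_table.dsa_true < 75.0,
        pred_pos=slice_table.dsa_pred < 75.0,
    ))

    level = (slice_table
             .groupby(["patient_id", "mode", "level"], as_index=False)
             .agg(dsa_pred=("dsa_pred", "min"), dsa_true=("dsa_true", "min")))
    level["pred_call"] = level.dsa_pred.map(classify_dichotomous)
    level["true_call"] = level.dsa_true.map(classify_dichotomous)
    level["pred_severe"] = level.dsa_pred.map(classify_severe)
    level["true_severe"] = level.dsa_true.map(classify_severe)
    cls_rows.append(_classification_row(
        "Level (narrowest)",
        truth_pos=level.dsa_true < 100.0,
        pred_pos=level.dsa_pred < 100.0,
    ))

    return EvalReport(
        segmentation=pd.DataFrame(seg_rows),
        classification=pd.DataFrame(cls_rows),
        slice_table=slice_table.reset_index(drop=True),
        level_table=level,
        notes=["level rows use the minimum DSA over the 11 slices of each level"],
    )
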
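"""Repeated-CV evaluation protocol and the three-hypothesis battery.

Every classifier is scored by 10x repeated stratified 5-fold
cross-validation (each test fold is the held-out 20%), yielding 50
per-split records of accuracy / precision / recall / F1 (macro-averaged,
in percent).  Three null hypotheses are then tested on the F1
distributions with Kruskal-Wallis at alpha = 0.05:

* H01 — a classifier does not beat the zero-rule baseline;
* H02 — adding emotion features (DS2) does not improve over brain-only
  (DS1);
* H03 — all classifiers perform alike (all-pairs mean-rank comparison
  with Dunn-Sidak familywise correction, reported as estimate + bounds).

KW is an omnibus test; the one-sided readings of H01/H02 are realised as
KW significance gated by the median pointing in the claimed direction.
The 50 CV records are treated as independent samples (folds of one repeat
share trials; caveat documented in the methods note).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import kruskal, norm, rankdata
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import RepeatedStratifiedKFold

from .models import ClassifierConfig, encode_labels, make_classifier
from .synthdata import CLASSES

__all__ = [
    "CVReport", "HypothesisReport", "compute_metrics",
    "repeated_stratified_cv", "kw_baseline_test", "kw_paired_datasets_test",
    "multicompare_dunn_sidak", "percent_change", "run_full_study",
]

ALPHA = 0.05


@dataclass
class CVReport:
    """Per-split metric records for one classifier under one condition."""

    records: pd.DataFrame   # columns: repeat, fold, accuracy, precision, recall, f1
    classifier: str
    variant: str = "DS1"
    kind: str = "rocket"
    seed: int = 0

    @property
    def f1(self) -> np.ndarray:
        return self.records["f1"].to_numpy()

    def summary(self) -> dict[str, str]:
        out = {"classifier": self.classifier, "variant": self.variant,
               "kind": self.kind}
        for m in ("accuracy", "precision", "recall", "f1"):
            col = self.records[m]
            out[m] = f"{col.mean():.2f} ± {col.std(ddof=1):.2f}"
        return out


@dataclass
class HypothesisReport:
    """Decisions for one hypothesis family."""

    hypothesis: str         # "H01" | "H02" | "H03"
    comparisons: list[dict] = field(default_factory=list)
    alpha: float = ALPHA


def compute_metrics(y_true, y_pred) -> tuple[float, float, float, float]:
    """(accuracy, macro precision, macro recall, macro F1), all in percent.

    A class never predicted yields an undefined per-class precision; the
    convention is 0 with a warning.
    """
    yt = encode_labels(y_true)
    yp = encode_labels(y_pred)
    if len(yt) != len(yp):
        raise ValueError("y_true and y_pred must have equal length")
    valid = set(range(len(CLASSES)))
    if not set(yt) <= valid or not set(yp) <= valid:
        raise ValueError("labels outside the 3-class set")
    if set(yt) - set(yp):
        warnings.warn(
            "some classes never predicted; their precision is taken as 0",
            stacklevel=2,
        )
    acc = float((yt == yp).mean())
    prec, rec, f1, _ = precision_recall_fscore_support(
        yt, yp, labels=list(range(len(CLASSES))), average="macro",
        zero_division=0,
    )
    return 100 * acc, 100 * float(prec), 100 * float(rec), 100 * float(f1)


def repeated_stratified_cv(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ClassifierConfig,
    n_repeats: int = 10,
    n_splits: int = 5,
    seed: int = 0,
    variant: str = "DS1",
    kind: str = "rocket",
    groups: np.ndarray | None = None,
) -> CVReport:
    """Score one classifier with repeated stratified k-fold CV.

    Each repeat reshuffles under a seed derived from ``seed``; the model is
    rebuilt and refit per fold and scored on the held-out fold.  With
    ``groups`` (participant ids) set, stratified *group* folds keep all of
    one participant's trials on the same side of each split.
    """
    X = np.asarray(X, dtype=float)
    yi = encode_labels(y)
    _, counts = np.unique(yi, return_counts=True)
    if counts.min() < n_splits:
        raise ValueError(
            f"every class needs >= {n_splits} members, got counts {counts}"
        )
    if groups is not None:
        from sklearn.model_selection import StratifiedGroupKFold

        def split_iter():
            for r in range(n_repeats):
                sgk = StratifiedGroupKFold(
                    n_splits=n_splits, shuffle=True, random_state=seed + r
                )
                for f, (tr, te) in enumerate(sgk.split(X, yi, groups)):
                    yield r, f, tr, te
    else:
        rskf = RepeatedStratifiedKFold(
            n_splits=n_splits, n_repeats=n_repeats, random_state=seed
        )

        def split_iter():
            for i, (tr, te) in enumerate(rskf.split(X, yi)):
                yield i // n_splits, i % n_splits, tr, te

    rows = []
    for r, f, tr, te in split_iter():
        fold_cfg = ClassifierConfig(
            name=cfg.name, params=dict(cfg.params),
            seed=cfg.seed + 1000 * r + f,
        )
        model = make_classifier(fold_cfg)
        model.fit(X[tr], yi[tr])
        acc, prec, rec, f1 = compute_metrics(yi[te], model.predict(X[te]))
        rows.append({"repeat": r, "fold": f, "accuracy": acc,
                     "precision": prec, "recall": rec, "f1": f1})
    return CVReport(
        records=pd.DataFrame(rows), classifier=cfg.name,
        variant=variant, kind=kind, seed=seed,
    )


def _kw_two_sample(a: np.ndarray, b: np.ndarray) -> float:
    """KW p-value robust to the degenerate all-identical case."""
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    return float(kruskal(a, b).pvalue)


def kw_baseline_test(
    report: CVReport, baseline: CVReport, alpha: float = ALPHA
) -> HypothesisReport:
    """H01: the classifier's F1 does not exceed the zero-rule baseline's.

    Rejected only when KW p < alpha AND the classifier's median F1 is above
    the baseline's (one-sided reading).
    """
    p = _kw_two_sample(report.f1, baseline.f1)
    direction = np.median(report.f1) > np.median(baseline.f1)
    rejected = (p < alpha) and direction
    return HypothesisReport(
        hypothesis="H01",
        comparisons=[{
            "classifier": report.classifier, "variant": report.variant,
            "p_value": p, "decision": "rejected" if rejected else "accepted",
        }],
        alpha=alpha,
    )


def kw_paired_datasets_test(
    report_ds1: CVReport, report_ds2: CVReport, alpha: float = ALPHA
) -> HypothesisReport:
    """H02: fusing emotion features (DS2) does not improve over DS1."""
    if report_ds1.classifier != report_ds2.classifier:
        raise ValueError("H02 compares one classifier across DS1/DS2")
    p = _kw_two_sample(report_ds1.f1, report_ds2.f1)
    direction = np.median(report_ds2.f1) > np.median(report_ds1.f1)
    rejected = (p < alpha) and direction
    return HypothesisReport(
        hypothesis="H02",
        comparisons=[{
            "classifier": report_ds1.classifier,
            "p_value": p, "decision": "rejected" if rejected else "accepted",
        }],
        alpha=alpha,
    )


def multicompare_dunn_sidak(
    reports: list[CVReport], alpha: float = ALPHA
) -> HypothesisReport:
    """H03 all-pairs comparison of mean F1 ranks with Dunn-Sidak bounds.

    All records are ranked jointly; for each classifier pair the mean-rank
    difference is reported with confidence bounds at the Sidak-adjusted
    per-comparison level 1-(1-alpha)^(1/m).  A pair is significant iff its
    interval excludes 0, equivalently iff its Sidak-adjusted p < alpha.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports")
    ns = [len(r.f1) for r in reports]
    if len(set(ns)) != 1:
        raise ValueError(f"unequal record counts {ns}")
    pooled = np.concatenate([r.f1 for r in reports])
    N = pooled.size
    ranks = rankdata(pooled)
    # tie correction for the rank variance
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t**3 - t).sum() / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term

    mean_ranks, idx = [], 0
    for r in reports:
        n = len(r.f1)
        mean_ranks.append(ranks[idx:idx + n].mean())
        idx += n

    pairs = list(combinations(range(len(reports)), 2))
    m = len(pairs)
    alpha_sidak = 1.0 - (1.0 - alpha) ** (1.0 / m)
    zcrit = norm.ppf(1.0 - alpha_sidak / 2.0)

    comparisons = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / ns[i] + 1.0 / ns[j]))
        diff = mean_ranks[i] - mean_ranks[j]
        z = diff / se if se > 0 else 0.0
        p_raw = 2.0 * (1.0 - norm.cdf(abs(z)))
        p_adj = min(1.0, 1.0 - (1.0 - p_raw) ** m)
        half = zcrit * se
        lower, upper = diff - half, diff + half
        significant = (lower > 0) or (upper < 0)
        comparisons.append({
            "a": reports[i].classifier, "b": reports[j].classifier,
            "estimate": diff, "lower": lower, "upper": upper,
            "p_value": p_adj,
            "decision": "rejected" if significant else "accepted",
        })
    return HypothesisReport(hypothesis="H03", comparisons=comparisons,
                            alpha=alpha)


def percent_change(before: float, after: float) -> float:
    """Relative change in percent, e.g. 50.79 -> 71.55 gives 40.87."""
    if before == 0:
        raise ValueError("undefined percent change from 0")
    return 100.0 * (after - before) / before


# ---------------------------------------------------------------------------
# End-to-end study orchestration
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    metrics: pd.DataFrame            # Table-3-shaped summary
    h01: list[HypothesisReport]
    h02: list[HypothesisReport]
    h03: dict[str, HypothesisReport]  # per variant (rocket features)
    pct_change: pd.DataFrame         # DS1 -> DS2 accuracy change per classifier
    reports: dict                    # (classifier, variant, kind) -> CVReport


def run_full_study(config) -> StudyResult:
    """Generate, preprocess, featurise, benchmark and test end-to-end.

    ``config`` is a :class:`neuroexpertise.config.StudyConfig`; reduced
    problem sizes (fewer repeats, fewer epochs) are plain config settings.
    """
    from .config import StudyConfig, derive_seed
    from .features import build_dataset
    from .fnirs_prep import preprocess_cohort
    from .synthdata import generate_cohort

    assert isinstance(config, StudyConfig)
    cohort = generate_cohort(config.cohort)
    pre = preprocess_cohort(cohort)

    matrices = {}
    for variant in ("DS1", "DS2"):
        for kind in ("statistical", "rocket"):
            matrices[(variant, kind)] = build_dataset(
                pre, variant=variant, kind=kind,
                n_kernels=config.features.n_kernels,
                seed=derive_seed(config.seed, f"features-{variant}-{kind}"),
            )

    ev = config.evaluation
    reports: dict = {}
    baselines: dict = {}
    for (variant, kind), fm in matrices.items():
        base_cfg = ClassifierConfig(
            name="baseline", seed=derive_seed(config.seed, "baseline")
        )
        baselines[(variant, kind)] = repeated_stratified_cv(
            fm.X, fm.y, base_cfg, n_repeats=ev.n_repeats,
            n_splits=ev.n_splits,
            seed=derive_seed(config.seed, f"cv-{variant}-{kind}"),
            variant=variant, kind=kind,
        )
        for name in config.models.classifiers:
            params = dict(config.models.params.get(name, {}))
            if name in ("FCDNN", "DCAE"):
                params.setdefault("variant", variant)
                params.setdefault("epochs", config.models.deep_epochs)
            cfg = ClassifierConfig(
                name=name, params=params,
                seed=derive_seed(config.seed, f"clf-{name}"),
            )
            reports[(name, variant, kind)] = repeated_stratified_cv(
                fm.X, fm.y, cfg, n_repeats=ev.n_repeats,
                n_splits=ev.n_splits,
                seed=derive_seed(config.seed, f"cv-{variant}-{kind}"),
                variant=variant, kind=kind,
            )

    metrics = pd.DataFrame(
        [r.summary() for r in reports.values()]
    )

    h01 = [
        kw_baseline_test(reports[(n, v, k)], baselines[(v, k)], alpha=ev.alpha)
        for (n, v, k) in reports
    ]
    h02 = [
        kw_paired_datasets_test(
            reports[(name, "DS1", kind)], reports[(name, "DS2", kind)],
            alpha=ev.alpha,
        )
        for name in config.models.classifiers
        for kind in ("rocket",)
    ]
    h03 = {
        variant: multicompare_dunn_sidak(
            [reports[(n, variant, "rocket")] for n in config.models.classifiers],
            alpha=ev.alpha,
        )
        for variant in ("DS1", "DS2")
        if len(config.models.classifiers) >= 2
    }

    pct_rows = []
    for name in config.models.classifiers:
        a = reports[(name, "DS1", "rocket")].records["accuracy"].mean()
        b = reports[(name, "DS2", "rocket")].records["accuracy"].mean()
        pct_rows.append({"classifier": name, "ds1_accuracy": a,
                         "ds2_accuracy": b,
                         "pct_change": percent_change(a, b)})
    pct = pd.DataFrame(pct_rows)

    return StudyResult(metrics=metrics, h01=h01, h02=h02, h03=h03,
                       pct_change=pct, reports=reports)
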
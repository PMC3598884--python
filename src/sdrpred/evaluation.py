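"""Benchmarking protocol: ROC/AUC, balanced resampling, per-protein
negatives, leave-one-allele-out cross-validation and ranking bins.

The headline statistic is the area under the ROC curve — the probability
that a positive example outscores a negative one — computed as the
Mann–Whitney U estimator with ties counted one half.  Balanced AUCs
resample as many negatives as there are positives, ten times by default,
from a larger negative pool.  Leave-one-allele-out cross-validation
removes one allele's binding data entirely and predicts it from the
remaining alleles through the SDR transfer, which is the honest test of
a pan-specific method: the query allele contributes nothing to its own
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .binding_db import BindingCoreStore
from .hla import SDRConfiguration
from .pwm import build_pwm


@dataclass(frozen=True)
class LabeledScoreSet:
    """Positive and negative score lists with provenance."""

    positives: tuple[float, ...]
    negatives: tuple[float, ...]
    allele: str = ""
    resample_seed: Optional[int] = None


def auc(scores: LabeledScoreSet) -> float:
    """Mann–Whitney AUC with midrank tie handling.

    Equals the trapezoidal area under the ROC curve and estimates
    P(score⁺ > score⁻) + ½·P(score⁺ = score⁻).
    """
    pos = np.asarray(scores.positives, dtype=float)
    neg = np.asarray(scores.negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs at least one positive and one negative score")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_points(scores: LabeledScoreSet) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve (false-positive rate, true-positive rate) as a monotone
    step set from (0,0) to (1,1)."""
    y = np.concatenate(
        [np.ones(len(scores.positives)), np.zeros(len(scores.negatives))]
    )
    s = np.concatenate([scores.positives, scores.negatives])
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    return fpr, tpr


def fractional_auc(
    roc: tuple[np.ndarray, np.ndarray], specificity_lo: float = 0.8
) -> float:
    """ROC area restricted to the high-specificity region.

    Integrates the curve over false-positive rate ∈ [0, 1−specificity_lo]
    (trapezoidal, with interpolation at the right boundary).  A perfect
    classifier attains 1−specificity_lo; the chance diagonal attains
    (1−specificity_lo)²/2.
    """
    fpr, tpr = np.asarray(roc[0], dtype=float), np.asarray(roc[1], dtype=float)
    fpr_hi = 1.0 - specificity_lo
    keep = fpr <= fpr_hi
    xs, ys = list(fpr[keep]), list(tpr[keep])
    if xs and xs[-1] < fpr_hi:
        # linearly interpolate the boundary point on the exiting segment
        idx = int(np.argmax(fpr > fpr_hi))
        x0, y0, x1, y1 = fpr[idx - 1], tpr[idx - 1], fpr[idx], tpr[idx]
        ys.append(y0 + (y1 - y0) * (fpr_hi - x0) / (x1 - x0))
        xs.append(fpr_hi)
    return float(np.trapezoid(ys, xs))


def balanced_auc(
    positives: Sequence[float],
    negative_pool: Sequence[float],
    repeats: int = 10,
    seed: int = 0,
) -> tuple[float, list[float]]:
    """Mean AUC over balanced resamples of the negative pool.

    Each repeat draws |positives| negatives without replacement under a
    per-repeat seed derived from the master seed, so results are
    reproducible and repeats are independent draws.
    """
    pos = tuple(float(x) for x in positives)
    pool = np.asarray(negative_pool, dtype=float)
    if pool.size < len(pos):
        raise ValueError(
            f"negative pool ({pool.size}) smaller than positives ({len(pos)})"
        )
    ss = np.random.SeedSequence(seed)
    per_repeat = []
    for child in ss.spawn(repeats):
        rng = np.random.default_rng(child)
        sample = rng.choice(pool, size=len(pos), replace=False)
        per_repeat.append(auc(LabeledScoreSet(pos, tuple(sample))))
    return float(np.mean(per_repeat)), per_repeat


def make_protein_negatives(protein: str, epitope: str) -> list[str]:
    """Per-protein negative construction: every window of the protein of
    the epitope's length, excluding windows identical to the epitope
    (wherever they occur)."""
    protein, epitope = protein.upper(), epitope.upper()
    if epitope not in protein:
        raise ValueError(f"epitope {epitope!r} does not occur in the protein")
    k = len(epitope)
    return [
        protein[i : i + k]
        for i in range(len(protein) - k + 1)
        if protein[i : i + k] != epitope
    ]


def shuffled_negatives(
    cores: Sequence[str], per_core: int = 3, seed: int = 0
) -> list[str]:
    """Negative pool of residue-shuffled versions of the positive cores
    (composition-preserving simple shuffles)."""
    rng = np.random.default_rng(seed)
    out = []
    for core in cores:
        letters = np.array(list(core))
        for _ in range(per_core):
            out.append("".join(rng.permutation(letters)))
    return out


@dataclass
class BenchmarkResult:
    """Per-allele cross-validation outcome."""

    allele: str
    n_pos: int
    auc_mean: float
    auc_per_repeat: list[float]
    roc: tuple[np.ndarray, np.ndarray]
    frac_auc: float
    evaluable: bool = True
    contributors: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class LOOReport:
    """Leave-one-allele-out cross-validation report.

    ``mean_auc`` averages the per-allele balanced AUCs; ``pooled_auc``
    pools every allele's positives and negatives into one score set
    before computing a single AUC — both conventions are reported because
    they can differ on unbalanced panels.
    """

    results: list[BenchmarkResult]
    mean_auc: float
    pooled_auc: float


def loo_allele_cv(
    store: BindingCoreStore,
    sdr_config: SDRConfiguration,
    background: Optional[np.ndarray] = None,
    repeats: int = 10,
    seed: int = 0,
    negative_pools: Optional[dict[str, Sequence[str]]] = None,
    negatives_per_core: int = 3,
) -> LOOReport:
    """Leave-one-allele-out cross-validation over the store.

    For each allele A: build A's PWM from the store minus A, score A's
    cores (positives) and a negative 9-mer pool — caller-supplied via
    ``negative_pools`` or, by default, residue-shuffled copies of the
    positives — then compute the balanced AUC over ``repeats`` resamples.
    An allele whose exclusion leaves every pocket pool empty is still
    scored (its degenerate matrix ties everything at 50.5, AUC 0.5) but
    flagged not evaluable.
    """
    alleles = store.alleles
    if len(alleles) < 2:
        raise ValueError("leave-one-allele-out needs at least two alleles")
    ss = np.random.SeedSequence(seed)
    results: list[BenchmarkResult] = []
    all_pos: list[float] = []
    all_neg: list[float] = []
    for allele, child in zip(alleles, ss.spawn(len(alleles))):
        sub = store.without_allele(allele)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # empty pockets are reported via flags
            pwm = build_pwm(store.profiles[allele], sub, sdr_config, background=background)
        contributors = {row.label: row.contributors for row in pwm.rows}
        evaluable = any(row.n_pool > 0 for row in pwm.rows)

        cores = [c.core for c in store.cores[allele]]
        if not cores:
            continue
        s1, s2 = child.generate_state(2) % (2**31)
        if negative_pools is not None and allele in negative_pools:
            neg_seqs = list(negative_pools[allele])
        else:
            neg_seqs = shuffled_negatives(cores, per_core=negatives_per_core, seed=int(s1))
        pos_scores = [pwm.normalized(pwm.score(c)) for c in cores]
        neg_scores = [pwm.normalized(pwm.score(s)) for s in neg_seqs]
        mean_auc, per_repeat = balanced_auc(
            pos_scores, neg_scores, repeats=repeats, seed=int(s2)
        )
        full = LabeledScoreSet(tuple(pos_scores), tuple(neg_scores), allele=allele)
        roc = roc_points(full)
        results.append(
            BenchmarkResult(
                allele=allele,
                n_pos=len(cores),
                auc_mean=mean_auc,
                auc_per_repeat=per_repeat,
                roc=roc,
                frac_auc=fractional_auc(roc),
                evaluable=evaluable,
                contributors=contributors,
            )
        )
        all_pos.extend(pos_scores)
        all_neg.extend(neg_scores)

    pooled = auc(LabeledScoreSet(tuple(all_pos), tuple(all_neg)))
    mean = float(np.mean([r.auc_mean for r in results]))
    return LOOReport(results=results, mean_auc=mean, pooled_auc=pooled)


def ranking_distribution(
    percentages: Sequence[float],
    bins: Sequence[float] = (1.0, 3.0, 5.0, 100.0),
) -> dict:
    """Bin epitope ranking percentages into (0,1], (1,3], (3,5], (5,100]
    fractions (the stacked-bar summary of immunodominant-epitope
    retrieval) plus the mean ± SD of the percentages."""
    vals = np.asarray(
        [getattr(p, "percentage", p) for p in percentages], dtype=float
    )
    if vals.size == 0:
        raise ValueError("no ranking results to bin")
    edges = np.concatenate([[0.0], np.asarray(bins, dtype=float)])
    fractions = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        fractions[f"({lo:g},{hi:g}]"] = float(np.mean((vals > lo) & (vals <= hi)))
    return {
        "fractions": fractions,
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
    }
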
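"""Region-level Shapley attribution and cohort group statistics.

Attribution treats each atlas region as one player in a cooperative game
whose payoff is the model's positive-class (MDD) probability.  A region is
"absent" when its values are replaced by the training-set mean (occlusion
baseline): for the time-series modality that is the region's pooled mean
signal, for the volume modality the per-voxel mean over subjects within the
region's parcel.  Shapley values are estimated by Monte-Carlo sampling of
region orderings (exact enumeration for small region counts), retaining the
sign of each region's average marginal contribution.

The statistics mirror a standard demographic comparison table: Welch
(unequal-variance) two-sample t-tests for continuous covariates — also
recomputable from published summary statistics — and a Yates
continuity-corrected chi-square for 2×2 sex-by-group counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import MultimodalNet
from .synthetic import CohortArrays
from .train_eval import _Prepared, _prepare, predict_scores

__all__ = ["ContingencyTable2x2", "shapley_values", "region_shapley",
           "welch_ttest", "welch_from_summary", "chisq_yates",
           "demographics_table"]


# ------------------------------------------------------------------- Shapley
def shapley_values(f, x: np.ndarray, baseline: np.ndarray,
                   groups: list[np.ndarray] | int,
                   n_permutations: int | None = 128,
                   seed: int = 0) -> np.ndarray:
    """Grouped Shapley attribution of ``f`` at point(s) ``x``.

    ``f`` maps an array shaped like ``x`` to a scalar payoff. ``groups``
    is either a list of index arrays into the trailing axes of ``x`` or an
    integer G meaning the last axis splits into G singleton groups.
    ``n_permutations=None`` enumerates all orderings exactly (small G only).
    Returns one signed value per group; exact values satisfy the efficiency
    identity sum(phi) = f(x) - f(baseline).
    """
    if isinstance(groups, int):
        groups = [np.array([g]) for g in range(groups)]
    G = len(groups)
    if n_permutations is not None and n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    if n_permutations is None:
        orders = list(itertools.permutations(range(G)))
    else:
        orders = [rng.permutation(G) for _ in range(n_permutations)]
    phi = np.zeros(G)

    def masked_input(present: np.ndarray) -> np.ndarray:
        z = baseline.copy()
        for g in np.flatnonzero(present):
            idx = groups[g]
            z[..., idx] = x[..., idx]
        return z

    for order in orders:
        present = np.zeros(G, dtype=bool)
        prev = f(masked_input(present))
        for g in order:
            present[g] = True
            cur = f(masked_input(present))
            phi[g] += cur - prev
            prev = cur
    return phi / len(orders)


def region_shapley(model: MultimodalNet, cohort: CohortArrays,
                   modality: str, parcel_map: np.ndarray | None = None,
                   n_permutations: int = 16, seed: int = 0,
                   subject_idx: np.ndarray | None = None,
                   prepared: _Prepared | None = None) -> pd.DataFrame:
    """Per-region Shapley attribution of the MDD probability, with a
    two-sample Welch test on each region's subject-level feature.

    Attribution is the signed mean over evaluated subjects of each region's
    Shapley value; the payoff of a coalition is the mean predicted MDD
    probability when absent regions are occluded with their training-set
    mean.  Regions are columns of the time series (``modality="ts"``) or
    parcels of the volume (``modality="gmv"``; ``parcel_map`` defaults to
    the cohort's own).
    """
    if modality not in ("ts", "gmv"):
        raise ValueError("modality must be 'ts' or 'gmv'")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if prepared is None:
        prepared = _prepare(cohort, np.arange(len(cohort)))
    if subject_idx is None:
        subject_idx = np.arange(len(cohort))
    subject_idx = np.asarray(subject_idx)
    d = cohort.ts[0].shape[1]
    rng = np.random.default_rng(seed)
    if parcel_map is None:
        parcel_map = cohort.parcel_map

    def eval_mean_prob(ts_list, gmv_stack) -> float:
        view = _Prepared(ts=ts_list, gmv=gmv_stack,
                         labels=prepared.labels[subject_idx],
                         sites=prepared.sites[subject_idx])
        scores = predict_scores(model, view, np.arange(len(subject_idx)))
        return float(scores.mean())

    base_ts = [prepared.ts[i] for i in subject_idx]
    base_gmv = prepared.gmv[subject_idx]

    if modality == "ts":
        mean_trace = np.concatenate(prepared.ts).mean(axis=0)  # per region
        region_feature = np.stack([prepared.ts[i].mean(axis=0)
                                   for i in subject_idx])

        def coalition_value(present: np.ndarray) -> float:
            absent = np.flatnonzero(~present)
            patched = []
            for s in base_ts:
                z = s.copy()
                z[:, absent] = mean_trace[absent]
                patched.append(z)
            return eval_mean_prob(patched, base_gmv)

        n_groups = d
    else:
        mean_vol = prepared.gmv.mean(axis=0)
        region_feature = np.stack([
            [prepared.gmv[i][parcel_map == r].mean() for r in range(d)]
            for i in subject_idx])

        def coalition_value(present: np.ndarray) -> float:
            patched = base_gmv.copy()
            for r in np.flatnonzero(~present):
                m = parcel_map == r
                patched[:, m] = mean_vol[m]
            return eval_mean_prob(base_ts, patched)

        n_groups = d

    # permutation-sampling Shapley over regions
    phi = np.zeros(n_groups)
    for _ in range(n_permutations):
        order = rng.permutation(n_groups)
        present = np.zeros(n_groups, dtype=bool)
        prev = coalition_value(present)
        for g in order:
            present[g] = True
            cur = coalition_value(present)
            phi[g] += cur - prev
            prev = cur
    phi /= n_permutations

    labels = prepared.labels[subject_idx]
    rows = []
    for r in range(n_groups):
        a = region_feature[labels == 1, r]
        b = region_feature[labels == 0, r]
        if len(a) >= 2 and len(b) >= 2:
            _, _, p = welch_ttest(a, b)
        else:  # degenerate subject subset: group test undefined
            p = float("nan")
        rows.append({"region": r, "modality": modality,
                     "attribution": phi[r], "p_value": p})
    df = pd.DataFrame(rows)
    return df.reindex(df["attribution"].abs()
                      .sort_values(ascending=False).index)


# ---------------------------------------------------------------- statistics
def welch_ttest(sample_a: np.ndarray, sample_b: np.ndarray
                ) -> tuple[float, float, float]:
    """Unequal-variance two-sample t-test.

    Returns (t, Welch–Satterthwaite degrees of freedom, two-sided p).
    Two constant, equal samples give t = 0, p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, \
            float(len(a) + len(b) - 2), 0.0
    se2 = va / len(a) + vb / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / (va ** 2 / (len(a) ** 2 * (len(a) - 1))
                     + vb ** 2 / (len(b) ** 2 * (len(b) - 1)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_from_summary(m1: float, s1: float, n1: int,
                       m2: float, s2: float, n2: int) -> float:
    """Welch t statistic from group means, SDs and sizes:
    t = (m1 − m2) / sqrt(s1²/n1 + s2²/n2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be >= 0")
    se2 = s1 ** 2 / n1 + s2 ** 2 / n2
    if se2 == 0:
        if m1 == m2:
            return 0.0
        return math.inf if m1 > m2 else -math.inf
    return (m1 - m2) / math.sqrt(se2)


@dataclass
class ContingencyTable2x2:
    """2×2 counts laid out as [[a, b], [c, d]] (rows = groups)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]],
                        dtype=np.float64)


def chisq_yates(table: ContingencyTable2x2, correction: bool = True
                ) -> tuple[float, float]:
    """Chi-square test of independence on a 2×2 table (df = 1).

    With ``correction=True`` (default) the Yates continuity correction
    subtracts 0.5 from each |O − E|, floored at zero.
    """
    obs = table.as_array()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("a zero marginal makes the statistic undefined")
    expected = np.outer(rows, cols) / total
    diff = np.abs(obs - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def demographics_table(records) -> pd.DataFrame:
    """Group comparison of age, education (Welch t) and sex (Yates χ²)
    between MDD and HC subjects of a manifest."""
    rows = []
    mdd = [r for r in records if r.label == 1]
    hc = [r for r in records if r.label == 0]
    for attr in ("age", "education"):
        a = np.array([getattr(r, attr) for r in mdd
                      if getattr(r, attr) is not None])
        b = np.array([getattr(r, attr) for r in hc
                      if getattr(r, attr) is not None])
        if len(a) >= 2 and len(b) >= 2:
            t, df, p = welch_ttest(a, b)
            rows.append({"characteristic": attr, "test": "welch_t",
                         "statistic": t, "p_value": p,
                         "mdd_mean": a.mean(), "hc_mean": b.mean()})
    sexes = [r.sex for r in records if r.sex is not None]
    if sexes:
        tab = ContingencyTable2x2(
            a=sum(1 for r in mdd if r.sex == "male"),
            b=sum(1 for r in mdd if r.sex == "female"),
            c=sum(1 for r in hc if r.sex == "male"),
            d=sum(1 for r in hc if r.sex == "female"))
        chi2, p = chisq_yates(tab)
        rows.append({"characteristic": "sex", "test": "chisq_yates",
                     "statistic": chi2, "p_value": p,
                     "mdd_mean": np.nan, "hc_mean": np.nan})
    return pd.DataFrame(rows)
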
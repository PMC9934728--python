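"""Per-feature significance statistics and grouped tree-ensemble importance.

Two Model/Results pairs:

* :class:`FeatureOLS` — one joint ordinary-least-squares regression of the
  binary label on the standardized feature matrix (plus intercept). The
  results carry per-feature coefficients, t and two-sided p values and
  standard errors, the global R², F statistic and log-likelihood under the
  Gaussian-error OLS convention, and a p-value histogram over the
  conventional significance thresholds. No multiple-testing correction is
  applied; thresholds are on raw p values.
* :class:`TreeImportance` — a single seeded Extremely-Randomized-Trees fit
  whose mean-decrease-in-impurity importances (normalized to sum to one) are
  averaged within groups of features: feature family, signal type, EEG
  channel, EEG PSD band. The ±1 SE bars are the standard error across the
  ensemble's trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.ensemble import ExtraTreesClassifier

from .features import (
    FeatureMatrix,
    feature_channel,
    feature_family,
    feature_signal,
)

__all__ = [
    "FeatureOLS",
    "FeatureOLSResults",
    "TreeImportance",
    "ImportanceResults",
    "bin_pvalues",
    "PVALUE_BINS",
]

#: Ordered exclusive p-value bins; a feature lands in the first bin whose
#: upper bound it is strictly below ("p = 0" means printed-zero, i.e. exact
#: double-precision zero after computation).
PVALUE_BINS = ("p = 0", "p < 0.001", "p < 0.01", "p < 0.05", "p > 0.05")


def bin_pvalues(pvalues: np.ndarray) -> dict[str, int]:
    """Count features per significance bin (mutually exclusive, in order)."""
    pvalues = np.asarray(pvalues, float)
    counts = dict.fromkeys(PVALUE_BINS, 0)
    for p in pvalues:
        if p == 0.0:
            counts["p = 0"] += 1
        elif p < 0.001:
            counts["p < 0.001"] += 1
        elif p < 0.01:
            counts["p < 0.01"] += 1
        elif p < 0.05:
            counts["p < 0.05"] += 1
        else:
            counts["p > 0.05"] += 1
    return counts


@dataclass
class FeatureOLSResults:
    """Per-feature OLS statistics plus global fit diagnostics."""

    feature_names: tuple[str, ...]
    params: np.ndarray       # coefficients (intercept excluded)
    bse: np.ndarray          # standard errors
    tvalues: np.ndarray
    pvalues: np.ndarray
    rsquared: float
    fvalue: float
    f_pvalue: float
    llf: float
    nobs: int

    def pvalue_bins(self) -> dict[str, int]:
        return bin_pvalues(self.pvalues)

    def summary(self) -> str:
        bins = self.pvalue_bins()
        lines = [
            "Per-feature OLS significance",
            "-" * 40,
            f"{'n epochs':<22}{self.nobs:>12d}",
            f"{'n features':<22}{len(self.feature_names):>12d}",
            f"{'R^2':<22}{self.rsquared:>12.4f}",
            f"{'F statistic':<22}{self.fvalue:>12.3f}",
            f"{'Prob (F)':<22}{self.f_pvalue:>12.3g}",
            f"{'Log-likelihood':<22}{self.llf:>12.2f}",
            "",
            f"{'p value range':<22}{'Count (#)':>12}",
        ]
        lines += [f"{name:<22}{count:>12d}" for name, count in bins.items()]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "rsquared": self.rsquared,
            "fvalue": self.fvalue,
            "f_pvalue": self.f_pvalue,
            "llf": self.llf,
            "nobs": self.nobs,
            "pvalue_bins": self.pvalue_bins(),
            "features": [
                {
                    "name": n,
                    "coef": float(b),
                    "se": float(s),
                    "t": float(t),
                    "p": float(p),
                }
                for n, b, s, t, p in zip(
                    self.feature_names, self.params, self.bse,
                    self.tvalues, self.pvalues,
                )
            ],
        }


class FeatureOLS:
    """Joint OLS of the binary label on standardized epoch features.

    Features are z-scored so that t values are scale-free across the mixed
    units of the three modalities. Constant features are kept at zero after
    standardization (their coefficients are reported as 0 with p = 1).

    Desk-scale cohorts can have fewer epochs than the 948 features; the fit
    then requires either ``feature_subset`` (column indices) or
    ``max_features`` (a seeded random subset) so the regression is
    well-posed — a rank-deficient design is otherwise solved by pseudo-
    inverse with a warning.

    ``marginal=True`` instead fits one simple regression per feature.
    """

    def __init__(
        self,
        fm: FeatureMatrix,
        feature_subset: np.ndarray | None = None,
        max_features: int | None = None,
        seed: int = 0,
        marginal: bool = False,
    ) -> None:
        if feature_subset is not None and max_features is not None:
            raise ValueError("give feature_subset or max_features, not both")
        if max_features is not None and max_features < fm.n_features:
            rng = np.random.default_rng(seed)
            feature_subset = np.sort(
                rng.choice(fm.n_features, size=max_features, replace=False)
            )
        self.fm = fm.subset(feature_subset) if feature_subset is not None else fm
        self.marginal = marginal
        if not self.marginal and self.fm.n_epochs <= self.fm.n_features + 1:
            raise ValueError(
                f"{self.fm.n_epochs} epochs cannot identify "
                f"{self.fm.n_features} joint coefficients; pass feature_subset/"
                "max_features or use marginal=True"
            )

    @staticmethod
    def _standardize(X: np.ndarray) -> np.ndarray:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0.0] = 1.0
        return (X - mu) / sd

    def fit(self) -> FeatureOLSResults:
        fm = self.fm
        Z = self._standardize(fm.X)
        y = fm.labels.astype(float)
        if self.marginal:
            p = fm.n_features
            params = np.empty(p)
            bse = np.empty(p)
            tvals = np.empty(p)
            pvals = np.empty(p)
            for j in range(p):
                res = sm.OLS(y, sm.add_constant(Z[:, j])).fit()
                params[j], bse[j] = res.params[1], res.bse[1]
                tvals[j], pvals[j] = res.tvalues[1], res.pvalues[1]
            full = sm.OLS(y, sm.add_constant(Z)).fit()  # global diagnostics
        else:
            full = sm.OLS(y, sm.add_constant(Z)).fit()
            params, bse = full.params[1:], full.bse[1:]
            tvals, pvals = full.tvalues[1:], full.pvalues[1:]
        return FeatureOLSResults(
            feature_names=fm.feature_names,
            params=np.asarray(params),
            bse=np.asarray(bse),
            tvalues=np.asarray(tvals),
            pvalues=np.asarray(pvals),
            rsquared=float(full.rsquared),
            fvalue=float(full.fvalue),
            f_pvalue=float(full.f_pvalue),
            llf=float(full.llf),
            nobs=int(full.nobs),
        )


GROUPINGS = ("family", "signal", "eeg_channel", "eeg_band")


def _group_key(name: str, grouping: str) -> str | None:
    if grouping == "family":
        return feature_family(name)
    if grouping == "signal":
        return feature_signal(name)
    if grouping == "eeg_channel":
        return feature_channel(name) if feature_signal(name) == "EEG" else None
    if grouping == "eeg_band":
        key = name.rsplit(".", 1)[-1]
        if feature_signal(name) == "EEG" and key.startswith("psd_"):
            return key.removeprefix("psd_")
        return None
    raise ValueError(f"unknown grouping {grouping!r}")


@dataclass
class ImportanceResults:
    """Grouped mean importance ± 1 SE for each grouping attribute."""

    per_feature: np.ndarray
    feature_names: tuple[str, ...]
    groups: dict[str, dict[str, tuple[float, float]]]  # grouping -> key -> (mean, se)
    n_trees: int

    def summary(self) -> str:
        lines = ["Grouped ERT feature importance (mean ± 1 SE)", "-" * 46]
        for grouping, table in self.groups.items():
            lines.append(f"[{grouping}]")
            for key, (mean, se) in sorted(
                table.items(), key=lambda kv: -kv[1][0]
            ):
                lines.append(f"  {key:<14}{mean:>12.3e} ± {se:.1e}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "groups": {
                grouping: {k: {"mean": m, "se": s} for k, (m, s) in table.items()}
                for grouping, table in self.groups.items()
            },
        }


class TreeImportance:
    """Grouped mean-decrease-in-impurity importance from one seeded ERT."""

    def __init__(
        self, fm: FeatureMatrix, seed: int = 0, n_estimators: int = 100
    ) -> None:
        if len(set(fm.labels.tolist())) < 2:
            raise ValueError("need both classes for importance analysis")
        self.fm = fm
        self.seed = seed
        self.n_estimators = n_estimators

    def fit(self) -> ImportanceResults:
        fm = self.fm
        est = ExtraTreesClassifier(
            n_estimators=self.n_estimators, random_state=self.seed
        )
        est.fit(fm.X, fm.labels)
        per_feature = est.feature_importances_  # normalized to sum to 1
        # per-tree normalized importances for the across-tree SE
        tree_imps = np.array([t.feature_importances_ for t in est.estimators_])
        n_trees = tree_imps.shape[0]
        groups: dict[str, dict[str, tuple[float, float]]] = {}
        for grouping in GROUPINGS:
            members: dict[str, list[int]] = {}
            for j, name in enumerate(fm.feature_names):
                key = _group_key(name, grouping)
                if key is not None:
                    members.setdefault(key, []).append(j)
            table = {}
            for key, idx in members.items():
                per_tree_mean = tree_imps[:, idx].mean(axis=1)
                table[key] = (
                    float(per_feature[idx].mean()),
                    float(per_tree_mean.std(ddof=1) / np.sqrt(n_trees)),
                )
            groups[grouping] = table
        return ImportanceResults(
            per_feature=per_feature,
            feature_names=fm.feature_names,
            groups=groups,
            n_trees=n_trees,
        )
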
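"""Statistics linking interaction calls to drug-pair characteristics.

Given a table of per-pair features (chemical similarity, target overlaps,
interactome distances, shared annotations, ...) labelled with the pair's
interaction status, this module quantifies which features distinguish
interaction types: Cohen's d effect sizes against the pooled standard
deviation, bootstrap distributions of group means, and per-feature
enrichment/depletion tests (Fisher's exact test for binary overlap
features, Mann-Whitney U otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cohens_d",
    "bootstrap_means",
    "BootstrapResult",
    "feature_association",
    "AssociationResult",
    "fingerprint",
]

LABEL_NONE = "none"
INTERACTION_LABELS = ("positive", "negative", "emergent")


def cohens_d(sample1, sample2) -> float:
    """Standardised mean difference (mu1 - mu2) / pooled s.d.

    The pooled standard deviation weights each group's variance by its
    degrees of freedom.  Antisymmetric under swapping the samples; NaN
    (flagged undefined) when the pooled s.d. is zero.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("Cohen's d needs at least 2 observations per group")
    s1, s2 = x.var(ddof=1), y.var(ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    if pooled == 0:
        return float("nan")
    return float((x.mean() - y.mean()) / pooled)


@dataclass
class BootstrapResult:
    means: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    n_boot: int

    @property
    def se(self) -> float:
        return float(self.means.std(ddof=1))


def bootstrap_means(
    sample,
    n_boot: int = 10_000,
    seed: int | None = None,
    ci: float = 95.0,
) -> BootstrapResult:
    """Bootstrap distribution of the sample mean.

    Resamples n values with replacement (n = sample size) ``n_boot``
    times; each resample contributes its mean.  Summarised by the mean of
    means and a percentile confidence interval.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    means = x[idx].mean(axis=1)
    tail = (100.0 - ci) / 2.0
    lo, hi = np.percentile(means, [tail, 100.0 - tail])
    return BootstrapResult(
        means=means, mean=float(means.mean()),
        ci_low=float(lo), ci_high=float(hi), n_boot=n_boot,
    )


@dataclass
class AssociationResult:
    feature: str
    type_label: str
    test: str                  # "fisher" | "mannwhitney"
    p_value: float
    effect: float              # odds ratio or fold-change of means
    direction: str             # "enriched" | "depleted" | "none"
    significant: bool


def feature_association(
    table: pd.DataFrame,
    feature: str,
    type_label: str,
    reference_label: str = LABEL_NONE,
    alpha: float = 0.05,
    binary: bool | None = None,
) -> AssociationResult:
    """Test one pair feature for association with one interaction type.

    Pairs labelled ``type_label`` are compared against pairs labelled
    ``reference_label`` (non-interacting pairs by default).  Binary
    features get Fisher's exact test with the odds ratio as effect;
    numeric features get the Mann-Whitney U test with the fold-change of
    group means.  Degenerate contingency tables (a feature constant in
    both groups) report p = 1 and direction "none".
    """
    g1 = table.loc[table["label"] == type_label, feature].dropna()
    g2 = table.loc[table["label"] == reference_label, feature].dropna()
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least 2 pairs per group")
    values = pd.concat([g1, g2])
    if binary is None:
        binary = set(np.unique(values)) <= {0, 1, False, True}

    if binary:
        a, b = int(g1.sum()), int((1 - g1).sum())
        c, d = int(g2.sum()), int((1 - g2).sum())
        if (a + c == 0) or (b + d == 0):
            return AssociationResult(feature, type_label, "fisher", 1.0,
                                     float("nan"), "none", False)
        odds, p = stats.fisher_exact([[a, b], [c, d]])
        effect = float(odds)
        higher = (a / max(a + b, 1)) > (c / max(c + d, 1))
    else:
        if values.nunique() == 1:
            return AssociationResult(feature, type_label, "mannwhitney", 1.0,
                                     float("nan"), "none", False)
        _, p = stats.mannwhitneyu(g1, g2, alternative="two-sided")
        mean2 = g2.mean()
        effect = float(g1.mean() / mean2) if mean2 != 0 else float("nan")
        higher = g1.mean() > mean2
    significant = bool(p <= alpha)
    direction = ("enriched" if higher else "depleted") if significant else "none"
    return AssociationResult(feature, type_label,
                             "fisher" if binary else "mannwhitney",
                             float(p), effect, direction, significant)


def fingerprint(table: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Cohen's d profile of each interaction type against all interactions.

    For every feature and every interaction type, the pairs of that type
    are compared with the pool of all interacting pairs; d = 0 means the
    type is indistinguishable from the interaction background on that
    feature.  Rows are (type, feature).
    """
    features = features or [c for c in table.columns if c != "label"]
    interacting = table[table["label"] != LABEL_NONE]
    rows = []
    for label in INTERACTION_LABELS:
        group = interacting[interacting["label"] == label]
        if len(group) < 2:
            continue
        for feature in features:
            rows.append(
                {
                    "type": label,
                    "feature": feature,
                    "cohens_d": cohens_d(
                        group[feature].dropna(), interacting[feature].dropna()
                    ),
                }
            )
    return pd.DataFrame(rows)
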
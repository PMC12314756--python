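"""Synthetic TDT cohort generation.

The study population this generator emulates is a school cohort of 806
students who completed a nine-item suicidal-ideation scale (0-90 points,
mean 17.19, SD 7.01) and a tree drawing coded for the 98 catalog features.
Binarizing the scale at mean + SD puts 94 subjects in the high-ideation
group (class 1) against 712 low-ideation subjects, an imbalance of ~7.57:1.

Because the original drawings and codes are not public, cohorts are simulated:
feature presences are class-conditional Bernoulli draws whose log-odds are
shifted for high-ideation subjects on a configurable set of signal-bearing
feature classes (default "leaf and flower", plus small nuisance shifts
everywhere so that every feature class carries a little information).  A
latent real-valued "signal" matrix (the coding matrix plus Gaussian noise)
stands in for the raster images consumed by the feature-extraction surrogate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .catalog import FeatureCatalog, build_feature_catalog

# Per-class baseline feature prevalence.  Chosen so that the expected number
# of present features per drawing is ~19, matching a bipartite graph of
# ~15.4k edges over 806 x 98 cells.
DEFAULT_BASE_PREVALENCE: dict[str, float] = {
    "overall": 0.21,
    "line": 0.22,
    "special mark": 0.08,
    "special tree type": 0.10,
    "canopy": 0.26,
    "branch": 0.18,
    "leaf and flower": 0.22,
    "trunk": 0.21,
    "junction": 0.18,
    "root": 0.12,
    "ground": 0.18,
    "attachment": 0.15,
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study cohort's size, imbalance, and scale moments.
    ``effect_size`` is the log-odds shift applied, for high-ideation subjects,
    to the prevalence of every feature in ``signal_classes``;
    ``nuisance_effect_sd`` is the SD of small per-feature log-odds shifts
    applied to all features so no class is entirely uninformative.
    """

    n_subjects: int = 806
    n_high: int = 94
    score_mean: float = 17.19
    score_sd: float = 7.01
    score_min: float = 0.0
    score_max: float = 90.0
    base_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_PREVALENCE)
    )
    effect_size: float = 2.0
    signal_classes: tuple[str, ...] = ("leaf and flower",)
    nuisance_effect_sd: float = 0.15
    signal_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.n_high < self.n_subjects:
            raise ValueError("need 0 < n_high < n_subjects")
        for cls, p in self.base_prevalence.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence for {cls!r} outside (0,1): {p}")
        if self.signal_noise_sd <= 0:
            raise ValueError("signal_noise_sd must be positive")


@dataclass
class Cohort:
    """A simulated TDT cohort.

    Z is the M x N binary coding matrix (rows = drawings, columns = catalog
    features), ``signals`` the latent per-feature evidence used by the
    extraction surrogate, ``scores`` the scale totals and ``labels`` the
    high/low ideation indicator (1 = high).
    """

    Z: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    signals: np.ndarray
    catalog: FeatureCatalog
    seed: int

    @property
    def n_subjects(self) -> int:
        return self.Z.shape[0]

    @property
    def image_ids(self) -> list[str]:
        return [f"img_{i + 1:04d}" for i in range(self.n_subjects)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.Z, index=self.image_ids, columns=self.catalog.feature_names
        )
        df["score"] = self.scores
        df["label"] = self.labels
        df.index.name = "image_id"
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def read_cohort_csv(path, catalog: FeatureCatalog | None = None) -> Cohort:
    """Read a cohort written by :meth:`Cohort.to_csv`.

    The latent signal matrix is not serialized; it is restored as Z itself
    (noise-free evidence).
    """
    catalog = catalog or build_feature_catalog()
    df = pd.read_csv(path, index_col=0)
    Z = df[catalog.feature_names].to_numpy(dtype=np.int8)
    return Cohort(
        Z=Z,
        scores=df["score"].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=np.int8),
        signals=Z.astype(float),
        catalog=catalog,
        seed=-1,
    )


def _feature_prevalences(
    catalog: FeatureCatalog, base_prevalence: dict[str, float]
) -> np.ndarray:
    p = np.empty(catalog.n_features)
    for _, cls in catalog.entries:
        if cls not in base_prevalence:
            raise ValueError(f"no base prevalence for class {cls!r}")
    for j, (_, cls) in enumerate(catalog.entries):
        p[j] = base_prevalence[cls]
    return p


def simulate_cohort(
    config: CohortConfig | None = None, catalog: FeatureCatalog | None = None
) -> Cohort:
    """Draw a cohort from the generator defined by ``config``.

    Scores come from a normal truncated to the scale range; the top ``n_high``
    scores are assigned to the high-ideation subjects so the label set is
    exactly consistent with a mean-plus-SD style cut while keeping the group
    size fixed by construction.  Feature presences are Bernoulli with
    per-feature prevalence shifted on the log-odds scale for high-ideation
    subjects (by ``effect_size`` on signal classes and by small random
    nuisance shifts everywhere).
    """
    config = config or CohortConfig()
    config.validate()
    catalog = catalog or build_feature_catalog()
    rng = np.random.default_rng(config.seed)

    m, n = config.n_subjects, catalog.n_features

    # Labels: n_high ones at random positions.
    labels = np.zeros(m, dtype=np.int8)
    high_idx = rng.choice(m, size=config.n_high, replace=False)
    labels[high_idx] = 1

    # Scores: truncated normal, then rank-matched to labels (top scores to
    # the high group) so label/score ordering is internally consistent.
    a = (config.score_min - config.score_mean) / config.score_sd
    b = (config.score_max - config.score_mean) / config.score_sd
    raw = stats.truncnorm.rvs(
        a, b, loc=config.score_mean, scale=config.score_sd, size=m, random_state=rng
    )
    sorted_scores = np.sort(raw)
    scores = np.empty(m)
    low_idx = np.flatnonzero(labels == 0)
    # bottom m-n_high scores shuffled over low group, top n_high over high group
    lo, hi = sorted_scores[: m - config.n_high], sorted_scores[m - config.n_high :]
    scores[low_idx] = rng.permutation(lo)
    scores[high_idx] = rng.permutation(hi)

    # Per-feature prevalence and high-group log-odds shifts.
    base_p = _feature_prevalences(catalog, config.base_prevalence)
    shift = rng.normal(0.0, config.nuisance_effect_sd, size=n)
    for cls in config.signal_classes:
        shift[catalog.class_indices(cls)] += config.effect_size
    p_low = base_p
    p_high = expit(logit(base_p) + shift)

    p_mat = np.where(labels[:, None] == 1, p_high[None, :], p_low[None, :])
    Z = (rng.random((m, n)) < p_mat).astype(np.int8)

    signals = Z + rng.normal(0.0, config.signal_noise_sd, size=(m, n))
    return Cohort(
        Z=Z, scores=scores, labels=labels, signals=signals,
        catalog=catalog, seed=config.seed,
    )


def threshold_labels(
    scores: np.ndarray, inclusive: bool = True
) -> np.ndarray:
    """Binarize scale scores at mean + sample SD (high ideation = 1).

    Uses the sample SD (denominator M-1).  The boundary is inclusive by
    default: a score exactly at the threshold is labeled high.  A zero-SD
    (constant) score vector is degenerate and triggers a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size < 2:
        raise ValueError("need a 1-D score vector of length >= 2")
    sd = scores.std(ddof=1)
    if sd == 0.0:
        warnings.warn(
            "constant score vector: mean + SD threshold is degenerate",
            stacklevel=2,
        )
    thr = scores.mean() + sd
    if inclusive:
        return (scores >= thr).astype(np.int8)
    return (scores > thr).astype(np.int8)


def corrupt_features(
    Z: np.ndarray, flip_01: float, flip_10: float, seed: int
) -> np.ndarray:
    """Flip coding-matrix cells independently: 0->1 w.p. flip_01, 1->0 w.p. flip_10.

    Emulates an imperfect automatic feature extractor acting on the true
    codes.
    """
    for name, p in (("flip_01", flip_01), ("flip_10", flip_10)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {p}")
    Z = np.asarray(Z)
    rng = np.random.default_rng(seed)
    u = rng.random(Z.shape)
    flip = np.where(Z == 1, u < flip_10, u < flip_01)
    return np.where(flip, 1 - Z, Z).astype(np.int8)
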
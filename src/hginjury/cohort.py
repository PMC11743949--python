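"""Synthetic athlete cohorts with the structure the analysis assumes.

The study squad (26 national-team athletes observed under traditional
training and under the male-assisted MAFT mode) is confidential, so every
downstream stage is exercised on synthetic cohorts that emulate its
structure: n=26 athletes, positions 3 centers / 3 defensive centers /
15 perimeter players / 5 goalkeepers, a 320-dimensional standardised feature
vector per athlete, 9 binary per-site injury labels, two training regimes,
and latent within-regime interaction groups that seed hyperedges.

Generative model (all randomness from one explicit seed):

* injury labels are multi-label Bernoulli per site, with default per-site
  rates equal to the observed per-mode injury proportions of the study
  squad (an athlete can carry several injuries — the observed proportions
  sum to well over 100%);
* features are class-conditional Gaussians: isotropic noise with the
  positive class of each site shifted by ``class_separation * noise_sd``
  along a site-specific random unit direction;
* MAFT-regime athletes are drawn with within-group spread scaled by
  ``1 / regime_compactness_ratio`` (ratio > 1 makes the MAFT cloud more
  compact, the structural effect the pattern pipeline is meant to detect);
* interaction groups are sampled within regime only — the MAFT programme
  changes sparring composition, so cross-regime groups would not occur.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from hginjury.hypergraph import Hypergraph
from hginjury.stats import MODES, SITES, InjuryCountTable

POSITIONS = ("center", "defensive_center", "perimeter", "goalkeeper")
#: Default squad composition: 3 centers, 3 defensive centers, 15 perimeter
#: players, 5 goalkeepers.
POSITION_COUNTS = (3, 3, 15, 5)

#: Per-site injury counts observed in the study squad (n=26 athletes per
#: mode): rows are the nine sites in :data:`hginjury.stats.SITES` order.
TABLE1_TRADITIONAL = (2, 9, 2, 1, 7, 11, 4, 0, 0)
TABLE1_MAFT = (1, 11, 7, 1, 9, 6, 3, 1, 1)


def table1_fixture() -> InjuryCountTable:
    """The study squad's per-site injury counts under both training modes."""
    return InjuryCountTable(
        sites=SITES,
        traditional=TABLE1_TRADITIONAL,
        maft=TABLE1_MAFT,
        n_per_mode=26,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    ``class_separation`` is the distance between the per-site class means in
    units of ``noise_sd``; ``regime_compactness_ratio`` is the ratio of
    within-cluster spread traditional:maft.  ``site_rates`` optionally fixes
    the per-mode injury rates as a (2, n_sites) array (rows: traditional,
    maft); by default the observed study-squad proportions are used when
    ``n_sites == 9``, else a flat 0.3.
    """

    n_athletes: int = 26
    n_features: int = 320
    n_sites: int = 9
    class_separation: float = 1.5
    noise_sd: float = 1.0
    regime_compactness_ratio: float = 2.0
    group_size_range: tuple[int, int] = (3, 6)
    seed: int = 0
    site_rates: tuple[tuple[float, ...], tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        if self.n_athletes <= 0 or self.n_features <= 0 or self.n_sites <= 0:
            raise ValueError("counts must be positive")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if not self.regime_compactness_ratio > 0:
            raise ValueError("regime_compactness_ratio must be > 0")
        lo, hi = self.group_size_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid group_size_range {self.group_size_range}")
        if self.site_rates is not None:
            r = np.asarray(self.site_rates, dtype=float)
            if r.shape != (2, self.n_sites):
                raise ValueError("site_rates must have shape (2, n_sites)")
            if ((r < 0) | (r > 1)).any():
                raise ValueError("site_rates must lie in [0, 1]")

    def rates(self) -> np.ndarray:
        """Per-mode, per-site injury rates, shape (2, n_sites)."""
        if self.site_rates is not None:
            return np.asarray(self.site_rates, dtype=float)
        if self.n_sites == len(SITES):
            return np.array([TABLE1_TRADITIONAL, TABLE1_MAFT], dtype=float) / 26.0
        return np.full((2, self.n_sites), 0.3)


@dataclass(frozen=True)
class AthleteCohort:
    """One synthetic squad: features, regime, per-site injury labels, groups."""

    athlete_id: np.ndarray
    position: np.ndarray
    regime: np.ndarray
    features: np.ndarray
    injury_labels: np.ndarray
    interaction_groups: tuple[tuple[int, ...], ...]
    sites: tuple[str, ...] = SITES
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        n = len(self.athlete_id)
        if self.features.ndim != 2 or self.features.shape[0] != n:
            raise ValueError("features must have one row per athlete")
        if self.injury_labels.shape != (n, len(self.sites)):
            raise ValueError("injury_labels must be (n_athletes, n_sites)")
        if not np.isin(self.injury_labels, (0, 1)).all():
            raise ValueError("injury labels must be binary")
        if not set(np.unique(self.regime)) <= set(MODES):
            raise ValueError(f"regime values must be in {MODES}")
        for grp in self.interaction_groups:
            if len(grp) == 0:
                raise ValueError("empty interaction group")
            if not all(0 <= i < n for i in grp):
                raise ValueError("interaction group member out of range")

    @property
    def n_athletes(self) -> int:
        return len(self.athlete_id)

    def regime_indices(self, mode: str) -> np.ndarray:
        return np.flatnonzero(self.regime == mode)


def _position_assignment(n: int, rng: np.random.Generator) -> np.ndarray:
    # scale the 3/3/15/5 squad composition to n by largest remainder
    frac = np.array(POSITION_COUNTS, dtype=float) / sum(POSITION_COUNTS)
    base = np.floor(frac * n).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(frac * n - base))
    base[order[:rem]] += 1
    labels = np.repeat(np.array(POSITIONS, dtype=object), base)
    return rng.permutation(labels)


def generate_cohort(config: SimulationConfig) -> AthleteCohort:
    """Draw one cohort from the generative model (deterministic in the seed)."""
    rng = np.random.default_rng(config.seed)
    n, d, s = config.n_athletes, config.n_features, config.n_sites

    position = _position_assignment(n, rng)

    # balanced regime split, order randomised
    n_trad = (n + 1) // 2
    regime = np.array(
        ["traditional"] * n_trad + ["maft"] * (n - n_trad), dtype=object
    )
    regime = rng.permutation(regime)
    is_maft = regime == "maft"

    rates = config.rates()
    mode_row = np.where(is_maft, 1, 0)
    labels = (rng.random((n, s)) < rates[mode_row]).astype(int)

    # site-specific unit directions for the class-mean offsets
    dirs = rng.normal(size=(s, d))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    noise = rng.normal(scale=config.noise_sd, size=(n, d))
    noise[is_maft] /= config.regime_compactness_ratio
    shift = config.class_separation * config.noise_sd
    features = noise + shift * (labels @ dirs)

    # every athlete trains in at least one group: partition each regime into
    # covering groups, then add overlapping groups up to ~2 per athlete
    groups: list[tuple[int, ...]] = []
    lo, hi = config.group_size_range
    mean_size = (lo + hi) / 2
    for mode in MODES:
        members = rng.permutation(np.flatnonzero(regime == mode))
        if len(members) == 0:
            continue
        n_before = len(groups)
        start = 0
        while start < len(members):
            size = min(int(rng.integers(lo, hi + 1)), len(members) - start)
            if 0 < len(members) - start - size < lo:
                size = len(members) - start  # absorb a too-small remainder
            groups.append(tuple(sorted(int(i) for i in members[start : start + size])))
            start += size
        n_extra = max(0, round(2 * len(members) / mean_size) - (len(groups) - n_before))
        for _ in range(n_extra):
            size = min(int(rng.integers(lo, hi + 1)), len(members))
            grp = rng.choice(members, size=size, replace=False)
            groups.append(tuple(sorted(int(i) for i in grp)))

    site_names = SITES if s == len(SITES) else tuple(f"site_{i}" for i in range(s))
    return AthleteCohort(
        athlete_id=np.arange(n),
        position=position,
        regime=regime,
        features=features,
        injury_labels=labels,
        interaction_groups=tuple(groups),
        sites=site_names,
        config=config,
    )


def hypergraph_from_groups(cohort: AthleteCohort) -> Hypergraph:
    """Hypergraph whose hyperedges are the cohort's interaction groups (w=1)."""
    return Hypergraph(
        n_vertices=cohort.n_athletes,
        hyperedges=cohort.interaction_groups,
    )


def sample_injury_counts(
    config: SimulationConfig, site_rates: np.ndarray | None = None
) -> InjuryCountTable:
    """Stochastic twin of the observed count table: binomial draws per site
    per mode at the given rates, denominator ``config.n_athletes``."""
    rng = np.random.default_rng(config.seed)
    rates = (
        np.asarray(site_rates, dtype=float) if site_rates is not None else config.rates()
    )
    if rates.shape != (2, config.n_sites):
        raise ValueError("site_rates must have shape (2, n_sites)")
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("rates must lie in [0, 1]")
    counts = rng.binomial(config.n_athletes, rates)
    site_names = (
        SITES
        if config.n_sites == len(SITES)
        else tuple(f"site_{i}" for i in range(config.n_sites))
    )
    return InjuryCountTable(
        sites=site_names,
        traditional=tuple(int(c) for c in counts[0]),
        maft=tuple(int(c) for c in counts[1]),
        n_per_mode=config.n_athletes,
    )


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience: the same study conditions under a different seed."""
    return replace(config, seed=seed)
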
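"""Cohort epidemiology and classifier evaluation statistics.

Per-site injury counts are compared between the two training modes
(traditional same-gender training vs. the male-assisted MAFT mode) with
two-tailed Fisher's exact tests at alpha = 0.05, and classifier performance
is summarised by the usual confusion-matrix metrics (ACC, PPV, NPV, SEN,
SPEC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from math import comb

#: The nine injury sites of the study cohort, in report order.
SITES: tuple[str, ...] = (
    "neck",
    "shoulder",
    "elbow_wrist",
    "chest_back",
    "lumbar_sacral_hip",
    "knee",
    "ankle",
    "forearm_ulnar",
    "sternoclavicular",
)

MODES: tuple[str, str] = ("traditional", "maft")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts for one injury site."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Confusion-matrix metrics ACC, PPV, NPV, SEN, SPEC.

    ACC = (TP+TN)/(TP+TN+FP+FN), PPV = TP/(TP+FP), NPV = TN/(TN+FN),
    SEN = TP/(TP+FN), SPEC = TN/(TN+FP).

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never as 0, so that macro averages over sites are not silently biased.
    """
    if c.total == 0:
        raise ValueError("all confusion counts are zero; metrics undefined")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "acc": (c.tp + c.tn) / c.total,
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
        "sen": ratio(c.tp, c.tp + c.fn),
        "spec": ratio(c.tn, c.tn + c.fp),
    }


@dataclass(frozen=True)
class InjuryCountTable:
    """Per-site injury counts under both training modes.

    ``traditional`` and ``maft`` hold one integer count per site; the
    denominator for proportions is the number of athletes observed under each
    mode (26 in the study cohort — the same squad before and after the MAFT
    programme was introduced).
    """

    sites: tuple[str, ...] = SITES
    traditional: tuple[int, ...] = field(default_factory=tuple)
    maft: tuple[int, ...] = field(default_factory=tuple)
    n_per_mode: int = 26

    def __post_init__(self) -> None:
        if len(self.traditional) != len(self.sites) or len(self.maft) != len(self.sites):
            raise ValueError("counts must have one entry per site")
        if self.n_per_mode <= 0:
            raise ValueError("n_per_mode must be positive")
        for counts in (self.traditional, self.maft):
            for c in counts:
                if not (0 <= c <= self.n_per_mode):
                    raise ValueError(f"count {c} outside [0, {self.n_per_mode}]")

    def count(self, site: str, mode: str) -> int:
        i = self.sites.index(site)
        if mode == "traditional":
            return self.traditional[i]
        if mode == "maft":
            return self.maft[i]
        raise KeyError(mode)


def _pct(count: int, n: int) -> float:
    # exact rational -> half-up to 1 decimal, matching the report formatting
    q = (Decimal(100) * Decimal(count) / Decimal(n)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


def proportions(t: InjuryCountTable) -> dict[str, dict[str, float]]:
    """Per-site injury proportions (percent of athletes per mode).

    Returns ``{site: {"traditional": pct, "maft": pct}}`` with percentages
    rounded half-up to one decimal (9/26 -> 34.6).
    """
    out: dict[str, dict[str, float]] = {}
    for i, site in enumerate(t.sites):
        out[site] = {
            "traditional": _pct(t.traditional[i], t.n_per_mode),
            "maft": _pct(t.maft[i], t.n_per_mode),
        }
    return out


def fisher_exact(table) -> float:
    """Two-tailed Fisher's exact p-value for a 2x2 contingency table.

    Uses the probability-mass convention: p is the sum over all tables with
    the observed margins whose hypergeometric probability does not exceed
    the observed table's.  Probabilities share the denominator C(N, col1),
    so the tie comparison is done on exact integer numerators — no float
    round-off can misclassify a near-tie.
    """
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n_total = a + b + c + d
    if n_total == 0:
        raise ValueError("table total must be positive")
    row1 = a + b
    col1 = a + c
    # support of the (1,1) cell given fixed margins
    lo = max(0, col1 - (n_total - row1))
    hi = min(row1, col1)
    numer = [comb(row1, x) * comb(n_total - row1, col1 - x) for x in range(lo, hi + 1)]
    obs = numer[a - lo]
    p = sum(v for v in numer if v <= obs) / comb(n_total, col1)
    return min(float(p), 1.0)


def compare_modes(t: InjuryCountTable, alpha: float = 0.05) -> list[dict]:
    """Fisher comparison of each site's injury proportion between modes.

    For each site the 2x2 table is
    ``[[injured_trad, uninjured_trad], [injured_maft, uninjured_maft]]``
    with per-mode denominator ``t.n_per_mode``.  Returns one record per site
    with the two-tailed p-value and a significance flag at ``alpha``.
    """
    n = t.n_per_mode
    report = []
    for i, site in enumerate(t.sites):
        ct, cm = t.traditional[i], t.maft[i]
        p = fisher_exact([[ct, n - ct], [cm, n - cm]])
        report.append({"site": site, "p": p, "significant": bool(p < alpha)})
    return report
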
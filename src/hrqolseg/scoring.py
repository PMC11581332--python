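"""EQ-5D index scoring and the Multiple Sclerosis Severity Score (MSSS).

EQ-5D profiles (five ordinal health domains) are converted to a utility
through a country-specific value set ("tariff"): a constant for full
health minus per-domain, per-level decrements.  The utility is then
linearly rescaled so the tariff's declared minimum maps to 0 and full
health to 100.  Value-set coefficients are licensed publications and
must be supplied by the user as a file; the package ships only a
clearly labelled synthetic toy tariff for testing.

The MSSS rank-normalises an EDSS disability score within strata of
equal (integer-year) disease duration: a person's MSSS measures how
severe their disability is relative to others who have had the disease
equally long, i.e. the speed of progression.  MSSS = 10 * midrank /
(n_stratum + 1), which maps into the open interval (0, 10).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ValueSetTable",
    "MsssParams",
    "score_eq5d",
    "compute_msss",
    "load_value_set",
    "toy_value_set",
]

EQ5D_DOMAINS = ("mobility", "self_care", "usual_activities", "pain_discomfort", "anxiety_depression")


@dataclass(frozen=True)
class ValueSetTable:
    """An EQ-5D value set: constant, per-domain level decrements, floor utility.

    ``decrements[domain][level]`` is the utility lost when the domain is
    at ``level``; level 1 (no problems) must have decrement 0.  ``u_min``
    is the tariff's declared minimum achievable utility, used as the
    zero point of the 0-100 index.
    """

    version: str
    constant: float
    decrements: dict[str, dict[int, float]]
    u_min: float

    def __post_init__(self) -> None:
        if not self.decrements:
            raise ValueError("value set declares no domains")
        for dom, levels in self.decrements.items():
            if levels.get(1, None) != 0.0:
                raise ValueError(f"domain {dom!r} must have decrement 0 at level 1")
        if self.constant != 1.0:
            raise ValueError("full-health profile must yield utility exactly 1")
        if not self.u_min < 1.0:
            raise ValueError("u_min must be below the full-health utility 1")
        worst = self.utility(self.worst_profile())
        if abs(worst - self.u_min) > 1e-9:
            raise ValueError(
                f"declared u_min {self.u_min} does not match the worst profile utility {worst}"
            )

    def levels(self, domain: str) -> list[int]:
        return sorted(self.decrements[domain])

    def worst_profile(self) -> dict[str, int]:
        return {d: max(lv, key=lambda k: lv[k]) for d, lv in self.decrements.items()}

    def utility(self, profile: dict[str, int]) -> float:
        u = self.constant
        for dom, levels in self.decrements.items():
            if dom not in profile:
                raise ValueError(f"profile lacks domain {dom!r}")
            lvl = int(profile[dom])
            if lvl not in levels:
                raise ValueError(
                    f"level {lvl} outside the tariff's range {sorted(levels)} for domain {dom!r}"
                )
            u -= levels[lvl]
        return u


def score_eq5d(profile: dict[str, int], value_set: ValueSetTable) -> float:
    """EQ-5D index on the 0-100 scale for one domain profile.

    The utility ``U = constant - sum(decrements)`` is rescaled linearly:
    ``index = 100 * (U - u_min) / (1 - u_min)`` so the tariff's worst
    profile scores 0 and full health scores 100.  Monotone non-increasing
    in every domain level.
    """
    u = value_set.utility(profile)
    return 100.0 * (u - value_set.u_min) / (1.0 - value_set.u_min)


@dataclass(frozen=True)
class MsssParams:
    """Stratification rule for the MSSS computation.

    Durations are binned to integer years; strata smaller than
    ``min_stratum_size`` are pooled with their nearest neighbouring
    strata, symmetrically outward (d±1, d±2, ...), until the minimum is
    met.
    """

    min_stratum_size: int = 5

    def __post_init__(self) -> None:
        if self.min_stratum_size < 2:
            raise ValueError("min_stratum_size must be at least 2")


def compute_msss(edss_values, durations, params: MsssParams = MsssParams()) -> np.ndarray:
    """Rank-normalised MSSS, one value per (EDSS, duration) pair.

    Within each pooled integer-year duration stratum, EDSS values get
    mid-ranks (ties share the mean rank); MSSS = 10 * midrank / (n + 1).
    NaN EDSS propagates to NaN MSSS.
    """
    edss = np.asarray(edss_values, dtype=float)
    dur = np.asarray(durations, dtype=float)
    if edss.shape != dur.shape:
        raise ValueError("EDSS and duration sequences must have equal length")
    if dur.size and np.nanmin(dur) < 0:
        raise ValueError("durations must be non-negative")
    observed = ~np.isnan(edss)
    out = np.full(edss.shape, np.nan)
    if observed.sum() == 0:
        return out
    if observed.sum() < params.min_stratum_size:
        raise ValueError(
            f"only {int(observed.sum())} observed EDSS values; cannot form a stratum "
            f"of size {params.min_stratum_size}"
        )
    bins = np.floor(dur[observed]).astype(int)
    idx = np.flatnonzero(observed)
    unique_bins = np.unique(bins)
    counts = {int(b): int((bins == b).sum()) for b in unique_bins}

    for b in unique_bins:
        members = [b]
        total = counts[int(b)]
        radius = 0
        while total < params.min_stratum_size:
            radius += 1
            grew = False
            for nb in (b - radius, b + radius):
                if int(nb) in counts:
                    members.append(int(nb))
                    total += counts[int(nb)]
                    grew = True
            if not grew and radius > int(np.max(unique_bins) - np.min(unique_bins)) + 1:
                raise ValueError("cannot pool duration strata to the minimum size")
        in_stratum = np.isin(bins, members)
        ranks = rankdata(edss[observed][in_stratum], method="average")
        msss_stratum = 10.0 * ranks / (in_stratum.sum() + 1)
        # pooled neighbours only provide reference ranks; values are
        # assigned to the rows whose own duration bin is b
        sel = np.flatnonzero(in_stratum)
        own = bins == b
        for pos, val in zip(sel, msss_stratum):
            if own[pos]:
                out[idx[pos]] = val
    return out


def load_value_set(csv_path, header_path=None) -> ValueSetTable:
    """Read a value set from a (domain, level, decrement) CSV plus a JSON
    header carrying the constant, declared minimum utility and version."""
    csv_path = Path(csv_path)
    if header_path is None:
        header_path = csv_path.with_suffix(".json")
    meta = json.loads(Path(header_path).read_text())
    tab = pd.read_csv(csv_path)
    required = {"domain", "level", "decrement"}
    if not required <= set(tab.columns):
        raise ValueError(f"value-set CSV must have columns {sorted(required)}")
    decs: dict[str, dict[int, float]] = {}
    for _, row in tab.iterrows():
        decs.setdefault(str(row["domain"]), {})[int(row["level"])] = float(row["decrement"])
    return ValueSetTable(
        version=str(meta.get("version", "unversioned")),
        constant=float(meta["constant"]),
        decrements=decs,
        u_min=float(meta["u_min"]),
    )


def toy_value_set() -> ValueSetTable:
    """A synthetic three-level toy tariff for tests and examples.

    Not a published value set; decrement magnitudes are merely plausible.
    """
    decs = {
        "mobility": {1: 0.0, 2: 0.10, 3: 0.30},
        "self_care": {1: 0.0, 2: 0.10, 3: 0.25},
        "usual_activities": {1: 0.0, 2: 0.08, 3: 0.20},
        "pain_discomfort": {1: 0.0, 2: 0.12, 3: 0.32},
        "anxiety_depression": {1: 0.0, 2: 0.10, 3: 0.28},
    }
    u_min = 1.0 - (0.30 + 0.25 + 0.20 + 0.32 + 0.28)
    return ValueSetTable(version="toy-synthetic-3L", constant=1.0, decrements=decs, u_min=u_min)
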
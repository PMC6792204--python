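"""FACT-B scoring and EQ-5D-5L tariff application.

The FACT-B (Functional Assessment of Cancer Therapy - Breast) is a 37-item
quality-of-life questionnaire with five subscales: physical wellbeing (PWB,
7 items), social/family wellbeing (SWB, 7 items), emotional wellbeing (EWB,
6 items), functional wellbeing (FWB, 7 items) and breast-cancer-specific
concerns (BCS, 10 items).  Items are answered 0-4; negatively worded items
are reverse-scored so that every subscale points "higher = better", giving
subscale maxima 28/28/24/28/40 and a total range of 0-148.

The EQ-5D-5L describes health on five dimensions (mobility, self-care, usual
activities, pain/discomfort, anxiety/depression), each at severity level 1
(no problems) to 5 (extreme problems).  A country-specific value set (tariff)
converts a profile into a utility anchored at 1 = full health; utilities may
be negative for states valued worse than dead.  Value sets are *data* here:
the package ships no tariff values and reads them from CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ScoringError, ValueSetError

DOMAINS: tuple[str, ...] = ("PWB", "SWB", "EWB", "FWB", "BCS")
DOMAIN_ITEM_COUNTS: dict[str, int] = {"PWB": 7, "SWB": 7, "EWB": 6, "FWB": 7, "BCS": 10}
DOMAIN_MAXIMA: dict[str, int] = {"PWB": 28, "SWB": 28, "EWB": 24, "FWB": 28, "BCS": 40}
N_ITEMS = 37
ITEM_MAX = 4
TOTAL_MAX = 148

EQ5D_DIMENSIONS: tuple[str, ...] = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)


def load_item_config(path: str | Path | None = None) -> pd.DataFrame:
    """Load the item -> (domain, polarity) assignment.

    The default configuration ships with the package and follows the standard
    FACIT orientation (PWB negatively worded, SWB/FWB positively worded, EWB
    and BCS mixed).  Custom configurations are CSV files with columns
    ``item,domain,polarity`` (polarity in {positive, negative}).
    """
    if path is None:
        ref = resources.files("utilmap").joinpath("data/factb_items_default.csv")
        with resources.as_file(ref) as p:
            cfg = pd.read_csv(p)
    else:
        cfg = pd.read_csv(path)
    _validate_item_config(cfg)
    return cfg


def _validate_item_config(cfg: pd.DataFrame) -> None:
    required = {"item", "domain", "polarity"}
    if not required.issubset(cfg.columns):
        raise ScoringError(f"item config must have columns {sorted(required)}")
    if len(cfg) != N_ITEMS or set(cfg["item"]) != set(range(1, N_ITEMS + 1)):
        raise ScoringError("item config must cover items 1..37 exactly once")
    counts = cfg["domain"].value_counts().to_dict()
    if counts != DOMAIN_ITEM_COUNTS:
        raise ScoringError(
            f"item counts per domain must be {DOMAIN_ITEM_COUNTS}, got {counts}"
        )
    bad = set(cfg["polarity"]) - {"positive", "negative"}
    if bad:
        raise ScoringError(f"unknown polarity values: {sorted(bad)}")


@dataclass(frozen=True)
class FactBResponse:
    """One respondent's raw FACT-B answers.

    ``item_values`` holds 37 entries in 0..4; ``None`` marks a missing item.
    ``domains`` and ``polarities`` assign each item (in order, item 1 first)
    to its subscale and wording direction.
    """

    item_values: tuple[int | None, ...]
    domains: tuple[str, ...]
    polarities: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.item_values) != N_ITEMS:
            raise ScoringError(f"expected {N_ITEMS} items, got {len(self.item_values)}")
        if len(self.domains) != N_ITEMS or len(self.polarities) != N_ITEMS:
            raise ScoringError("domain/polarity assignments must cover all 37 items")
        for d, expect in DOMAIN_ITEM_COUNTS.items():
            got = sum(1 for x in self.domains if x == d)
            if got != expect:
                raise ScoringError(f"domain {d} must have {expect} items, got {got}")
        for v in self.item_values:
            if v is not None and (not isinstance(v, (int,)) or not 0 <= v <= ITEM_MAX):
                raise ScoringError(f"item value {v!r} outside 0..{ITEM_MAX}")

    @classmethod
    def from_items(
        cls,
        item_values: Sequence[int | None],
        config: pd.DataFrame | None = None,
    ) -> "FactBResponse":
        """Build a response from item values plus an item-config table."""
        cfg = config if config is not None else load_item_config()
        _validate_item_config(cfg)
        cfg = cfg.sort_values("item")
        vals = tuple(None if pd.isna(v) else int(v) for v in item_values)
        return cls(vals, tuple(cfg["domain"]), tuple(cfg["polarity"]))


@dataclass(frozen=True)
class FactBScores:
    """Subscale totals and grand total on the 0-148 FACT-B scale."""

    pwb: float
    swb: float
    ewb: float
    fwb: float
    bcs: float
    total: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.total is None:
            object.__setattr__(
                self, "total", self.pwb + self.swb + self.ewb + self.fwb + self.bcs
            )
        for name in ("pwb", "swb", "ewb", "fwb", "bcs"):
            v = getattr(self, name)
            mx = DOMAIN_MAXIMA[name.upper()]
            if not 0 <= v <= mx:
                raise ScoringError(f"{name.upper()} = {v} outside 0..{mx}")
        s = self.pwb + self.swb + self.ewb + self.fwb + self.bcs
        if abs(self.total - s) > 1e-9:
            raise ScoringError(f"total {self.total} != sum of subscales {s}")

    def as_dict(self) -> dict[str, float]:
        return {
            "PWB": self.pwb,
            "SWB": self.swb,
            "EWB": self.ewb,
            "FWB": self.fwb,
            "BCS": self.bcs,
            "TOTAL": self.total,
        }


def _contribution(value: int, polarity: str) -> int:
    # Positively worded items score as answered; negatively worded reverse.
    return value if polarity == "positive" else ITEM_MAX - value


def score_factb(response: FactBResponse, prorate: bool = True) -> FactBScores:
    """Score a FACT-B response into subscale totals.

    With ``prorate=True`` (the FACIT convention) a subscale with missing items
    is scored as (mean contribution of answered items) x (item count) provided
    at least 50% of its items were answered; otherwise scoring fails.  With
    ``prorate=False`` any missing item is an error.
    """
    per_domain: dict[str, list[int]] = {d: [] for d in DOMAINS}
    missing: dict[str, int] = {d: 0 for d in DOMAINS}
    for value, domain, polarity in zip(
        response.item_values, response.domains, response.polarities
    ):
        if value is None:
            missing[domain] += 1
        else:
            per_domain[domain].append(_contribution(value, polarity))

    subscales: dict[str, float] = {}
    for d in DOMAINS:
        n_items = DOMAIN_ITEM_COUNTS[d]
        answered = per_domain[d]
        if missing[d] == 0:
            subscales[d] = float(sum(answered))
        elif not prorate:
            raise ScoringError(
                f"subscale {d}: {missing[d]} missing item(s) and prorating disabled"
            )
        elif len(answered) * 2 >= n_items:
            subscales[d] = sum(answered) / len(answered) * n_items
        else:
            raise ScoringError(
                f"subscale {d}: only {len(answered)}/{n_items} items answered "
                "(< 50%, cannot prorate)"
            )
    return FactBScores(
        pwb=subscales["PWB"],
        swb=subscales["SWB"],
        ewb=subscales["EWB"],
        fwb=subscales["FWB"],
        bcs=subscales["BCS"],
    )


def read_factb_items_csv(
    path: str | Path, config: pd.DataFrame | None = None, prorate: bool = True
) -> pd.DataFrame:
    """Score an item-level CSV (columns ``id,item01..item37``) into subscales.

    Returns a frame with columns ``id,pwb,swb,ewb,fwb,bcs,total``.
    """
    raw = pd.read_csv(path)
    item_cols = [f"item{i:02d}" for i in range(1, N_ITEMS + 1)]
    missing_cols = [c for c in item_cols if c not in raw.columns]
    if missing_cols:
        raise ScoringError(f"{path}: missing item columns {missing_cols[:3]}...")
    cfg = config if config is not None else load_item_config()
    rows = []
    for _, row in raw.iterrows():
        resp = FactBResponse.from_items([row[c] for c in item_cols], cfg)
        s = score_factb(resp, prorate=prorate)
        rows.append(
            {
                "id": row.get("id", _),
                "pwb": s.pwb,
                "swb": s.swb,
                "ewb": s.ewb,
                "fwb": s.fwb,
                "bcs": s.bcs,
                "total": s.total,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Eq5dProfile:
    """An EQ-5D-5L descriptive state in canonical coding (1 = no problems)."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for dim in EQ5D_DIMENSIONS:
            lvl = getattr(self, dim)
            if not (isinstance(lvl, int) and 1 <= lvl <= 5):
                raise ValueSetError(f"{dim} level {lvl!r} outside 1..5")

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return (
            self.mobility,
            self.self_care,
            self.usual_activities,
            self.pain_discomfort,
            self.anxiety_depression,
        )

    @classmethod
    def from_levels(cls, levels: Sequence[int]) -> "Eq5dProfile":
        return cls(*map(int, levels))


def recode_severity(profile: Eq5dProfile) -> tuple[int, int, int, int, int]:
    """Reversed-coding view: 6 - level, so 5 = no problems.

    This is the coding used when correlating EQ-5D dimensions with FACT-B
    subscales (both then point "higher = better"); it is an involution and
    never feeds the tariff lookup, which uses canonical coding.
    """
    return tuple(6 - lvl for lvl in profile.levels)  # type: ignore[return-value]


class UtilityValueSet:
    """A tariff converting EQ-5D-5L profiles to utilities.

    Two representations are supported:

    * *full table*: an explicit map from each of the 3125 profiles (or any
      subset) to its utility;
    * *additive*: per-dimension, per-level decrements subtracted from 1, the
      shape of most published EQ-5D-5L value sets.

    The full-health profile (1,1,1,1,1) must map to exactly 1 in either form.
    """

    def __init__(
        self,
        table: Mapping[tuple[int, ...], float] | None = None,
        decrements: Mapping[str, Mapping[int, float]] | None = None,
    ) -> None:
        if (table is None) == (decrements is None):
            raise ValueSetError("provide exactly one of table / decrements")
        self._table = dict(table) if table is not None else None
        self._decrements = None
        if decrements is not None:
            self._decrements = {d: dict(v) for d, v in decrements.items()}
            for dim in EQ5D_DIMENSIONS:
                levels = self._decrements.setdefault(dim, {})
                levels.setdefault(1, 0.0)
                if abs(levels[1]) > 1e-12:
                    raise ValueSetError(f"{dim} level-1 decrement must be 0")
                for lvl, dec in levels.items():
                    if dec < 0:
                        raise ValueSetError(
                            f"{dim} level {lvl}: negative decrement {dec}"
                        )
        if self._table is not None:
            full = self._table.get((1, 1, 1, 1, 1))
            if full is None or abs(full - 1.0) > 1e-12:
                raise ValueSetError("full-health profile must map to exactly 1")
            if any(u > 1 + 1e-12 for u in self._table.values()):
                raise ValueSetError("utilities must not exceed 1")

    @property
    def form(self) -> str:
        return "full" if self._table is not None else "additive"

    def utility(self, profile: Eq5dProfile) -> float:
        if self._table is not None:
            try:
                return float(self._table[profile.levels])
            except KeyError:
                raise ValueSetError(
                    f"profile {profile.levels} not covered by the value set"
                ) from None
        assert self._decrements is not None
        total = 0.0
        for dim, lvl in zip(EQ5D_DIMENSIONS, profile.levels):
            try:
                total += self._decrements[dim][lvl]
            except KeyError:
                raise ValueSetError(f"no decrement for {dim} level {lvl}") from None
        return 1.0 - total

    @classmethod
    def from_csv(cls, path: str | Path) -> "UtilityValueSet":
        """Read a value set from CSV.

        Full form: columns ``mo,sc,ua,pd,ad,utility``.
        Additive form: columns ``dimension,level,decrement``.
        """
        df = pd.read_csv(path)
        if {"mo", "sc", "ua", "pd", "ad", "utility"}.issubset(df.columns):
            table = {
                (int(r.mo), int(r.sc), int(r.ua), int(r.pd), int(r.ad)): float(
                    r.utility
                )
                for r in df.itertuples()
            }
            return cls(table=table)
        if {"dimension", "level", "decrement"}.issubset(df.columns):
            decs: dict[str, dict[int, float]] = {}
            for r in df.itertuples():
                decs.setdefault(str(r.dimension), {})[int(r.level)] = float(r.decrement)
            return cls(decrements=decs)
        raise ValueSetError(
            f"{path}: unrecognised value-set schema (columns {list(df.columns)})"
        )


def apply_value_set(profile: Eq5dProfile, value_set: UtilityValueSet) -> float:
    """Convert an EQ-5D-5L profile to a utility through a tariff."""
    return value_set.utility(profile)


def all_profiles() -> Iterable[Eq5dProfile]:
    """Iterate over the full 5^5 = 3125 profile space."""
    from itertools import product

    for levels in product(range(1, 6), repeat=5):
        yield Eq5dProfile.from_levels(levels)
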
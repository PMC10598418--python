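"""Effort-standardised catch/bycatch rates and depth-binned rate tables.

Effort is measured in *standardised trossa-days*: one reference trossa of
2000 m² net area (net length × number of nets × net height) soaking for one
day.  Catch per unit effort (CPUE) and bycatch per unit effort (BPUE) are
counts divided by the effort actually expended, rescaled to the reference
area, so boats fishing different gear sizes are directly comparable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError
from .records import FleetDataset, TrossaRecord

#: Reference trossa area (m²) to which all rates are standardised.
REFERENCE_AREA = 2000.0


def trossa_area(r: TrossaRecord) -> float:
    """Net area of a trossa in m²: net length × number of nets × net height."""
    if r.net_length <= 0 or r.n_nets < 1 or r.net_height <= 0:
        raise DomainError(
            f"non-positive trossa geometry: length={r.net_length}, "
            f"n_nets={r.n_nets}, height={r.net_height}"
        )
    return r.net_length * r.n_nets * r.net_height


def standardized_rate(
    count: float, area: float, soak_days: float, ref_area: float = REFERENCE_AREA
) -> float:
    """Count per reference-trossa-day: count / (area × soak) × ref_area."""
    if area <= 0:
        raise DomainError(f"area must be positive, got {area}")
    if soak_days < 1:
        raise DomainError(f"soak_days must be >= 1, got {soak_days}")
    if count < 0:
        raise DomainError(f"count must be non-negative, got {count}")
    return count / (area * soak_days) * ref_area


def standardized_trossa_days(r: TrossaRecord, ref_area: float = REFERENCE_AREA) -> float:
    """Effort of one record in standardised trossa-days (area × soak / ref area)."""
    if r.soak_days < 1:
        raise DomainError(f"record soak of {r.soak_days} days is < 1")
    return trossa_area(r) * r.soak_days / ref_area


@dataclass
class RateTable:
    """Per-depth-bin rates of fish catch and bird/mammal bycatch.

    ``edges`` are ascending lower bin edges in metres; bins are half-open
    ``[lower, upper)`` and the last bin is open above its lower edge
    (e.g. edges ``0,10,…,50`` give bins 0–10 … 40–50 and >50).  Undefined
    rates (no effort observed in a bin) are NaN, never silently zero.

    ``landings_proportion`` — the fraction of national annual landings taken
    in each bin — is the bridge from landings statistics to fleet-wide effort
    and is supplied externally.  ``effort`` (standardised trossa-days) and
    ``annual_bird_bycatch`` (individuals per year per bin) are optional
    companions carried when known.
    """

    edges: np.ndarray
    fish_rate: np.ndarray
    bird_rate: np.ndarray
    mammal_rate: np.ndarray
    landings_proportion: np.ndarray | None = None
    effort: np.ndarray | None = None
    annual_bird_bycatch: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.ndim != 1 or len(self.edges) < 1:
            raise DomainError("edges must be a non-empty 1-d array of lower bounds")
        if np.any(np.diff(self.edges) <= 0):
            raise DomainError("edges must be strictly ascending")
        n = len(self.edges)
        for name in ("fish_rate", "bird_rate", "mammal_rate"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise DomainError(f"{name} must have one entry per bin")
            if np.any(arr[~np.isnan(arr)] < 0):
                raise DomainError(f"{name} must be non-negative")
            setattr(self, name, arr)
        for name in ("landings_proportion", "effort", "annual_bird_bycatch"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n,):
                    raise DomainError(f"{name} must have one entry per bin")
                setattr(self, name, arr)
        if self.landings_proportion is not None:
            p = self.landings_proportion
            if np.any(p < 0):
                raise DomainError("landings proportions must be non-negative")
            if abs(p.sum() - 1.0) > 1e-9:
                raise DomainError(
                    f"landings proportions must sum to 1, got {p.sum():.12f}"
                )

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    @property
    def upper(self) -> np.ndarray:
        """Upper bin bounds; infinity for the open top bin."""
        return np.append(self.edges[1:], np.inf)

    @property
    def labels(self) -> list[str]:
        out = [f"{lo:g}-{hi:g}" for lo, hi in zip(self.edges[:-1], self.edges[1:])]
        out.append(f">{self.edges[-1]:g}")
        return out

    def bin_index(self, depth: float) -> int:
        if depth < self.edges[0]:
            raise DomainError(f"depth {depth} below the first bin edge {self.edges[0]}")
        return int(np.searchsorted(self.edges, depth, side="right")) - 1

    def replace(self, **changes) -> "RateTable":
        return dataclasses.replace(self, **changes)

    # -- serialisation ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "depth_lo": self.edges,
                "depth_hi": self.upper,
                "fish_rate": self.fish_rate,
                "bird_rate": self.bird_rate,
                "mammal_rate": self.mammal_rate,
                "landings_proportion": (
                    self.landings_proportion
                    if self.landings_proportion is not None
                    else np.nan
                ),
            }
        )
        if self.effort is not None:
            df["effort"] = self.effort
        if self.annual_bird_bycatch is not None:
            df["annual_bird_bycatch"] = self.annual_bird_bycatch
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RateTable":
        df = pd.read_csv(path)
        for col in ("depth_lo", "fish_rate", "bird_rate", "mammal_rate"):
            if col not in df.columns:
                raise SchemaError(f"rate table missing column {col!r}")
        prop = None
        if "landings_proportion" in df.columns:
            p = df["landings_proportion"].to_numpy(dtype=float)
            prop = None if np.all(np.isnan(p)) else p
        kwargs = {}
        for extra in ("effort", "annual_bird_bycatch"):
            if extra in df.columns:
                kwargs[extra] = df[extra].to_numpy(dtype=float)
        return cls(
            edges=df["depth_lo"].to_numpy(dtype=float),
            fish_rate=df["fish_rate"].to_numpy(dtype=float),
            bird_rate=df["bird_rate"].to_numpy(dtype=float),
            mammal_rate=df["mammal_rate"].to_numpy(dtype=float),
            landings_proportion=prop,
            **kwargs,
        )


def depth_binned_rates(
    d: FleetDataset,
    bin_width: float = 10.0,
    top_open_at: float = 50.0,
    standardised: bool = True,
) -> RateTable:
    """Pooled per-depth-bin rates: Σ counts / Σ trossa-days within each bin.

    Rates are effort-weighted totals, not means of per-trossa rates, so
    (bin rate × bin effort) always sums back to the raw count.  With
    ``standardised`` (the default) the denominator is standardised
    trossa-days; otherwise raw trossa-days (soak only).  Bins with no effort
    get NaN rates.  ``landings_proportion`` is left unset — it comes from
    published landings statistics, not from trial data.
    """
    if bin_width <= 0 or top_open_at <= 0:
        raise DomainError("bin_width and top_open_at must be positive")
    edges = np.arange(0.0, top_open_at + bin_width / 2, bin_width)
    n = len(edges)
    effort = np.zeros(n)
    fish = np.zeros(n)
    birds = np.zeros(n)
    mammals = np.zeros(n)
    for r in d.records:
        if not r.mean_depth > 0:
            raise DomainError(f"record in trip {r.trip_id} has non-positive depth")
        i = min(int(np.searchsorted(edges, r.mean_depth, side="right")) - 1, n - 1)
        e = standardized_trossa_days(r) if standardised else float(r.soak_days)
        effort[i] += e
        fish[i] += r.lumpfish_count
        birds[i] += r.total_birds
        mammals[i] += r.total_mammals
    with np.errstate(invalid="ignore", divide="ignore"):
        empty = effort == 0
        fish_rate = np.where(empty, np.nan, fish / np.where(empty, 1, effort))
        bird_rate = np.where(empty, np.nan, birds / np.where(empty, 1, effort))
        mammal_rate = np.where(empty, np.nan, mammals / np.where(empty, 1, effort))
    return RateTable(
        edges=edges,
        fish_rate=fish_rate,
        bird_rate=bird_rate,
        mammal_rate=mammal_rate,
        effort=effort,
    )
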
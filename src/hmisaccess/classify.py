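"""Service-provision cube, temporal trends, and facility functional classes.

A facility *provides* a service in a year when its aggregated count for that
indicator is greater than zero, and is *operational* in a year when it
provides at least one of the six studied indicators. From the resulting
boolean facility × year × indicator cube the module derives yearly provision
percentages (overall and by facility type), a total spatio-temporal
functional classification of each facility, the ownership × type
composition table, and an r×c Fisher exact test of ownership against
functional class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import gammaln

from .config import (
    ELIGIBLE_TYPES,
    FACILITY_TYPES,
    FUNCTIONAL_CLASSES,
    INDICATORS,
    OWNERSHIPS,
    YEARS,
)
from .hmis_io import UnknownReferenceError


class DegenerateTableError(ValueError):
    """Contingency table with an all-zero row or column."""


# ---------------------------------------------------------------------------
# Provision cube
# ---------------------------------------------------------------------------

def provision_cube(records: pd.DataFrame, registry: pd.DataFrame) -> xr.DataArray:
    """Boolean facility × year × indicator cube, complete over the registry.

    A missing record row means the service was not provided (False); a
    record for a facility absent from the registry raises.
    """
    facilities = registry["facility_id"].tolist()
    unknown = set(records["facility_id"]) - set(facilities)
    if unknown:
        raise UnknownReferenceError(
            f"service records reference unknown facility id(s): {sorted(unknown)[:5]}"
        )
    cube = xr.DataArray(
        np.zeros((len(facilities), len(YEARS), len(INDICATORS)), dtype=bool),
        dims=("facility", "year", "indicator"),
        coords={"facility": facilities, "year": list(YEARS), "indicator": list(INDICATORS)},
    )
    provided = records[records["count"] > 0]
    if len(provided):
        fidx = pd.Index(facilities).get_indexer(provided["facility_id"])
        yidx = provided["year"].to_numpy() - YEARS[0]
        iidx = pd.Index(INDICATORS).get_indexer(provided["indicator"])
        cube.values[fidx, yidx, iidx] = True
    return cube


def operational(cube: xr.DataArray) -> xr.DataArray:
    """Facility × year flag: provided at least one studied indicator."""
    return cube.any("indicator")


# ---------------------------------------------------------------------------
# Temporal trends
# ---------------------------------------------------------------------------

def percent_providing(
    cube: xr.DataArray,
    registry: pd.DataFrame,
    year: int,
    indicator: str,
    facility_type: str | None = None,
) -> float:
    """Percent of operational facilities providing ``indicator`` in ``year``.

    The denominator is the number of operational facilities that year (of
    ``facility_type`` when given); service-specific type eligibility is
    enforced — caesarean rates are computed over hospitals only. Returns NaN
    with a warning when the denominator is zero.
    """
    if year not in YEARS:
        raise ValueError(f"year {year} outside study span {YEARS[0]}-{YEARS[-1]}")
    if indicator not in INDICATORS:
        raise ValueError(f"unknown indicator {indicator!r}")

    eligible = ELIGIBLE_TYPES.get(indicator, FACILITY_TYPES)
    types = registry.set_index("facility_id")["type"].reindex(cube.coords["facility"].values)
    mask = types.isin(eligible).to_numpy()
    if facility_type is not None:
        mask &= (types == facility_type).to_numpy()

    op = operational(cube).sel(year=year).to_numpy() & mask
    denom = int(op.sum())
    if denom == 0:
        warnings.warn(
            f"no operational eligible facilities for {indicator} in {year}; percent undefined",
            stacklevel=2,
        )
        return float("nan")
    num = int((cube.sel(year=year, indicator=indicator).to_numpy() & op).sum())
    return 100.0 * num / denom


def percent_providing_table(cube: xr.DataArray, registry: pd.DataFrame) -> pd.DataFrame:
    """Tidy provision-percentage table over year × indicator × facility type
    ('all' pools every eligible type)."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for year in YEARS:
            for indicator in INDICATORS:
                scopes = ["all", *ELIGIBLE_TYPES.get(indicator, FACILITY_TYPES)]
                for scope in scopes:
                    pct = percent_providing(
                        cube, registry, year, indicator,
                        None if scope == "all" else scope,
                    )
                    rows.append(
                        {"year": year, "indicator": indicator,
                         "facility_type": scope, "percent": pct}
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Functional classification
# ---------------------------------------------------------------------------

def classify_facility(history: xr.DataArray) -> str:
    """Assign one functional class to a facility's year × indicator history.

    Rule order: no_service; closed (operational at the start year but not
    the end year); newly_operational (the reverse); oscillating (neither
    endpoint, some year between); facilities operational at both endpoints
    but with a gap year are the residual other_intermittent; facilities
    operational every year split into existing_{unchanged, increased,
    decreased, varying} on their start/end indicator sets.
    """
    pres = history.transpose("year", "indicator").to_numpy()
    op = pres.any(axis=1)
    if not op.any():
        return "no_service"
    first, last = bool(op[0]), bool(op[-1])
    if first and not last:
        return "closed"
    if not first and last:
        return "newly_operational"
    if not first and not last:
        return "oscillating"
    if not op.all():
        return "other_intermittent"
    if (pres == pres[0]).all():
        return "existing_unchanged"
    n16, n22 = int(pres[0].sum()), int(pres[-1].sum())
    if n22 > n16:
        return "existing_increased"
    if n16 > n22:
        return "existing_decreased"
    return "existing_varying"


def classify_all(cube: xr.DataArray) -> pd.Series:
    """Functional class per facility (index = facility_id)."""
    labels = {
        str(fac): classify_facility(cube.sel(facility=fac))
        for fac in cube.coords["facility"].values
    }
    return pd.Series(labels, name="functional_class")


def class_distribution(classes: pd.Series, registry: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per functional class, overall and by type."""
    merged = registry[["facility_id", "type"]].merge(
        classes.rename("functional_class"), left_on="facility_id", right_index=True
    )
    rows = []
    groups = [("all", merged)] + [
        (t, merged[merged["type"] == t]) for t in FACILITY_TYPES
    ]
    for scope, sub in groups:
        n = len(sub)
        counts = sub["functional_class"].value_counts()
        for cls in FUNCTIONAL_CLASSES:
            c = int(counts.get(cls, 0))
            rows.append(
                {
                    "facility_type": scope,
                    "functional_class": cls,
                    "count": c,
                    "percent": (100.0 * c / n) if n else float("nan"),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ownership × type composition
# ---------------------------------------------------------------------------

@dataclass
class OwnershipTypeTable:
    """Facility type × ownership counts with the derived percentage views."""

    counts: pd.DataFrame  # index: facility types present; columns: ownerships

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def within_type_pct(self) -> pd.DataFrame:
        """Each cell as a percent of its facility-type row."""
        return 100.0 * self.counts.div(self.counts.sum(axis=1), axis=0)

    @property
    def within_ownership_pct(self) -> pd.DataFrame:
        """Each cell as a percent of its ownership column."""
        return 100.0 * self.counts.div(self.counts.sum(axis=0), axis=1)

    @property
    def ownership_share_pct(self) -> pd.Series:
        """Each ownership's share of all facilities."""
        return 100.0 * self.counts.sum(axis=0) / self.grand_total

    @property
    def type_share_pct(self) -> pd.Series:
        """Each facility type's share of all facilities."""
        return 100.0 * self.counts.sum(axis=1) / self.grand_total


def ownership_type_table(registry: pd.DataFrame) -> OwnershipTypeTable:
    counts = (
        pd.crosstab(registry["type"], registry["ownership"])
        .reindex(index=list(FACILITY_TYPES), columns=list(OWNERSHIPS), fill_value=0)
        .astype(int)
    )
    counts.index.name = "type"
    counts.columns.name = "ownership"
    return OwnershipTypeTable(counts)


# ---------------------------------------------------------------------------
# Fisher exact test for r x c tables
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    p_value: float
    table_shape: tuple[int, int]
    method: str  # "exact_enumeration" | "monte_carlo"
    n_tables: int | None = None
    n_draws: int | None = None
    seed: int | None = None


_LOGP_SLACK = 1e-7  # relative slack when comparing table log-probabilities


def _log_prob_terms(row_sums: np.ndarray, col_sums: np.ndarray) -> float:
    n = int(row_sums.sum())
    return float(gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(n + 1))


def _enumerate_tables(row_sums: list[int], col_sums: list[int], cap: int):
    """Yield every non-negative integer table with the given margins.

    Raises ``_CapExceeded`` once more than ``cap`` tables have been yielded.
    """
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=np.int64)
    count = 0

    def fill(i: int, remaining_cols: list[int]):
        nonlocal count
        if i == r - 1:
            for j in range(c):
                table[i, j] = remaining_cols[j]
            if all(v >= 0 for v in remaining_cols):
                count += 1
                if count > cap:
                    raise _CapExceeded
                yield table
            return
        # enumerate row i left to right with feasibility bounds
        def fill_row(j: int, row_rem: int, cols: list[int]):
            if j == c - 1:
                if 0 <= row_rem <= cols[j]:
                    table[i, j] = row_rem
                    new_cols = cols.copy()
                    new_cols[j] -= row_rem
                    yield from fill(i + 1, new_cols)
                return
            hi = min(row_rem, cols[j])
            for v in range(hi + 1):
                table[i, j] = v
                new_cols = cols.copy()
                new_cols[j] -= v
                yield from fill_row(j + 1, row_rem - v, new_cols)

        yield from fill_row(0, row_sums[i], remaining_cols)

    yield from fill(0, list(col_sums))


class _CapExceeded(Exception):
    pass


def fisher_exact(
    table: np.ndarray | list,
    max_tables: int = 200_000,
    n_draws: int = 20_000,
    seed: int = 0,
) -> FisherResult:
    """Fisher's exact test for an r×c contingency table.

    When the number of fixed-margin tables is at most ``max_tables``, the
    p-value is the exact sum of hypergeometric probabilities of tables no
    more probable than the observed one. Larger problems fall back to a
    seeded Monte-Carlo permutation estimate with ``n_draws`` draws.
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2:
        raise ValueError("table must be 2-D")
    if (obs < 0).any():
        raise ValueError("table entries must be non-negative integers")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise DegenerateTableError("table has an all-zero row or column")

    const = _log_prob_terms(row_sums, col_sums)
    lfact = gammaln(np.arange(int(row_sums.sum()) + 1) + 1.0)  # lfact[k] = log k!
    logp_obs = const - float(lfact[obs].sum())
    threshold = logp_obs + _LOGP_SLACK

    # upper bound on the enumeration size: compositions of each row margin
    # (the last row is determined); skip enumeration when clearly too large
    c = obs.shape[1]
    bound = 1.0
    for rs in row_sums[:-1]:
        bound *= math.comb(int(rs) + c - 1, c - 1)
    if bound <= max_tables:
        try:
            total = 0.0
            n_tables = 0
            for t in _enumerate_tables(row_sums.tolist(), col_sums.tolist(), max_tables):
                n_tables += 1
                lp = const - float(lfact[t].sum())
                if lp <= threshold:
                    total += math.exp(lp)
            return FisherResult(
                p_value=min(1.0, total),
                table_shape=obs.shape,
                method="exact_enumeration",
                n_tables=n_tables,
            )
        except _CapExceeded:
            pass

    # Monte-Carlo permutation: shuffle row labels against fixed column labels
    rng = np.random.default_rng(seed)
    r, c = obs.shape
    n = int(row_sums.sum())
    row_labels = np.repeat(np.arange(r), row_sums)
    col_labels = np.repeat(np.arange(c), col_sums)
    hits = 0
    batch = 2_000
    done = 0
    while done < n_draws:
        b = min(batch, n_draws - done)
        perms = rng.permuted(np.tile(row_labels, (b, 1)), axis=1)
        idx = perms * c + col_labels[None, :]
        counts = np.zeros((b, r * c), dtype=np.int64)
        np.add.at(counts, (np.repeat(np.arange(b), n), idx.ravel()), 1)
        logps = const - gammaln(counts + 1).sum(axis=1)
        hits += int((logps <= threshold).sum())
        done += b
    return FisherResult(
        p_value=hits / n_draws,
        table_shape=obs.shape,
        method="monte_carlo",
        n_draws=n_draws,
        seed=seed,
    )
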
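"""From trajectories to connectivity: arrivals, flux, c(i,j), recruitment.

An arrival is the first 6-hourly output sample at which a living particle
lies inside an MPA boundary polygon (boundary-inclusive; samples after death
or domain exit never count).  From arrivals we derive:

* dispersal flux d(i) = r(i) / sum_i r(i), the share of all arrival events
  occurring in MPA i (an accessibility measure; the absolute normalization
  r(i)/released is reported alongside as ``d_abs``);
* connection probability c(i,j) = fraction of particles released at MPA i
  with an arrival record at MPA j;
* self-recruitment selfr(i) = c(i,i) / sum_j c(i,j) and subsidy recruitment
  subr(i) = sum_{j != i} c(i,j) / sum_j c(i,j), which always sum to 1 where
  MPA i has any connection.  The default normalizes over outgoing
  connections (row-wise); an 'incoming' orientation (column-wise) is
  available and results are labeled with the orientation used.

Multi-species aggregation adds matrices with equal total weight for the
threatened and the economic group (0.5 each, split equally within group).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import shapely

from larvanet.errors import ConsistencyError
from larvanet.lagrangian import ALIVE, ParticleEnsemble
from larvanet.registry import MPASite, SpeciesParams

ARRIVAL_COLUMNS = ["particle", "origin_mpa", "visited_mpa",
                   "record_index", "time", "alive_at_entry"]
DEMOGRAPHIC_THRESHOLD = 0.001  # connection probability relevant to demography


@dataclass
class ConnectivityResult:
    """Connectivity quantities for one species run or an aggregate."""

    species_name: str  # species or "aggregate"
    c_matrix: pd.DataFrame  # rows = origin, columns = destination
    d_flux: pd.DataFrame  # columns r, d, d_abs
    recruitment: pd.DataFrame  # columns selfr, subr, defined
    released_per_origin: dict[str, int]
    orientation: str = "outgoing"
    no_arrivals: bool = False


def detect_arrivals(ensemble: ParticleEnsemble, registry: list[MPASite],
                    mode: str = "any_time") -> pd.DataFrame:
    """First-entry arrival records for every (particle, MPA) pair.

    ``mode`` 'any_time' scans every output sample during the PLD (the
    default: arrivals are cumulative entries); 'end_of_pld' keeps only the
    final sample (settlement-only variant).
    Returns a DataFrame with columns ARRIVAL_COLUMNS, one row per pair.
    """
    if mode not in ("any_time", "end_of_pld"):
        raise ValueError(f"unknown arrival mode '{mode}'")
    known = {s.mpa_id for s in registry}
    unknown = set(np.unique(ensemble.origin_mpa)) - known
    if unknown:
        raise ConsistencyError(f"ensemble origins not in registry: {sorted(unknown)}")

    if mode == "end_of_pld":
        rec_indices = [ensemble.n_records - 1]
    else:
        rec_indices = range(ensemble.n_records)

    lon, lat, status = ensemble.lon, ensemble.lat, ensemble.status
    rows = []
    for site in registry:
        minx, miny, maxx, maxy = site.boundary.bounds
        shapely.prepare(site.boundary)  # speeds up repeated containment tests
        found = np.zeros(ensemble.n_particles, dtype=bool)
        for r in rec_indices:
            candidates = ((status[:, r] == ALIVE) & ~found
                          & (lon[:, r] >= minx) & (lon[:, r] <= maxx)
                          & (lat[:, r] >= miny) & (lat[:, r] <= maxy))
            idx = np.flatnonzero(candidates)
            if idx.size == 0:
                continue
            # boundary-inclusive containment
            hit = shapely.intersects_xy(site.boundary, lon[idx, r], lat[idx, r])
            entered = idx[hit]
            found[entered] = True
            for p in entered:
                rows.append((int(p), ensemble.origin_mpa[p], site.mpa_id,
                             int(r), ensemble.record_times[r], True))
    df = pd.DataFrame(rows, columns=ARRIVAL_COLUMNS)
    return df.sort_values(["particle", "record_index"], ignore_index=True)


def dispersal_flux(arrivals: pd.DataFrame, released_total: int,
                   mpa_ids: list[str]) -> pd.DataFrame:
    """Dispersal flux per MPA: d(i) = r(i) / sum r(i).

    r(i) counts arrival records in MPA i.  ``d_abs`` = r(i)/released_total
    is the released-total normalization, reported separately.  When no
    arrivals exist, d is all-zero and the frame carries
    ``attrs['no_arrivals'] = True``.
    """
    if released_total <= 0:
        raise ValueError("released_total must be positive")
    r = (arrivals.groupby("visited_mpa").size()
         .reindex(mpa_ids, fill_value=0).astype(float))
    total = r.sum()
    out = pd.DataFrame({"r": r.astype(int),
                        "d": r / total if total > 0 else r * 0.0,
                        "d_abs": r / released_total})
    out.index.name = "mpa_id"
    out.attrs["no_arrivals"] = bool(total == 0)
    return out


def connection_matrix(arrivals: pd.DataFrame,
                      released_per_origin: dict[str, int],
                      mpa_ids: list[str]) -> pd.DataFrame:
    """c(i,j): fraction of particles released at i that arrived at j.

    The diagonal counts particles inside their origin polygon at any output
    sample after release (including the release sample), so a zero-flow run
    yields the identity on occupied MPAs.
    """
    bad = set(arrivals["origin_mpa"].unique()) - set(released_per_origin)
    if bad:
        raise ConsistencyError(f"arrival origins without release counts: {sorted(bad)}")
    for origin, count in released_per_origin.items():
        if count <= 0:
            raise ValueError(f"non-positive release count for {origin}")
    counts = (arrivals.groupby(["origin_mpa", "visited_mpa"])["particle"]
              .nunique().unstack(fill_value=0)
              .reindex(index=mpa_ids, columns=mpa_ids, fill_value=0)
              .astype(float))
    released = pd.Series({m: released_per_origin.get(m, np.nan) for m in mpa_ids})
    c = counts.div(released, axis=0).fillna(0.0)
    c.index.name = "origin"
    c.columns.name = "destination"
    return c


def recruitment_fractions(c_matrix: pd.DataFrame,
                          orientation: str = "outgoing") -> pd.DataFrame:
    """Self- and subsidy-recruitment fractions per MPA.

    'outgoing' (default) normalizes over each origin row: selfr(i) =
    c(i,i)/sum_j c(i,j).  'incoming' normalizes over each destination
    column: selfr(i) = c(i,i)/sum_j c(j,i) — subsidy as larval replenishment
    received from other MPAs.  MPAs with zero total connection are flagged
    ``defined = False`` with fractions reported as 0 (no NaN propagation).
    """
    if orientation not in ("outgoing", "incoming"):
        raise ValueError(f"unknown orientation '{orientation}'")
    c = c_matrix.to_numpy(dtype=float)
    if c.shape[0] != c.shape[1]:
        raise ValueError("c_matrix must be square")
    diag = np.diag(c)
    totals = c.sum(axis=1) if orientation == "outgoing" else c.sum(axis=0)
    defined = totals > 0
    selfr = np.zeros_like(totals)
    subr = np.zeros_like(totals)
    selfr[defined] = diag[defined] / totals[defined]
    subr[defined] = (totals[defined] - diag[defined]) / totals[defined]
    out = pd.DataFrame({"selfr": selfr, "subr": subr, "defined": defined},
                       index=c_matrix.index)
    out.index.name = "mpa_id"
    out.attrs["orientation"] = orientation
    return out


def category_weights(species: list[SpeciesParams]) -> dict[str, float]:
    """Equal-proportion weights: each category gets 0.5, split within group."""
    groups: dict[str, list[str]] = {}
    for sp in species:
        groups.setdefault(sp.category, []).append(sp.name)
    n_groups = len(groups)
    weights = {}
    for members in groups.values():
        for name in members:
            weights[name] = 1.0 / (n_groups * len(members))
    return weights


def aggregate_species(results: dict[str, pd.DataFrame],
                      weights: dict[str, float]) -> pd.DataFrame:
    """Weighted sum of per-species c-matrices; weights must sum to 1."""
    if set(results) != set(weights):
        raise ValueError("weights must cover exactly the aggregated species")
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {total!r}")
    names = list(results)
    ref = results[names[0]]
    agg = sum(weights[n] * results[n].reindex_like(ref) for n in names)
    agg.index.name = ref.index.name
    agg.columns.name = ref.columns.name
    return agg


def connectivity_result(species_name: str, arrivals: pd.DataFrame,
                        released_per_origin: dict[str, int],
                        mpa_ids: list[str],
                        orientation: str = "outgoing") -> ConnectivityResult:
    """Bundle flux, c-matrix, and recruitment fractions for one run."""
    released_total = sum(released_per_origin.values())
    flux = dispersal_flux(arrivals, released_total, mpa_ids)
    c = connection_matrix(arrivals, released_per_origin, mpa_ids)
    rec = recruitment_fractions(c, orientation=orientation)
    return ConnectivityResult(
        species_name=species_name, c_matrix=c, d_flux=flux, recruitment=rec,
        released_per_origin=dict(released_per_origin),
        orientation=orientation,
        no_arrivals=bool(flux.attrs.get("no_arrivals", False)),
    )


def edge_list(c_matrix: pd.DataFrame, threshold: float = 0.0) -> pd.DataFrame:
    """Off-diagonal connections above ``threshold`` as (origin, destination,
    weight, demographic) rows, for the network stage and export."""
    rows = []
    for i in c_matrix.index:
        for j in c_matrix.columns:
            if i == j:
                continue
            w = float(c_matrix.loc[i, j])
            if w > threshold:
                rows.append((i, j, w, w >= DEMOGRAPHIC_THRESHOLD))
    return pd.DataFrame(rows, columns=["origin", "destination", "weight",
                                       "demographic"])
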
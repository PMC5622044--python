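"""Environmentally extended linked multi-regional input-output (MRIO) algebra.

The linked table couples a block of domestic regions (provinces) with a block
of foreign regions (countries) in one square inter-industry flow matrix.
Embodied emissions follow the standard Leontief attribution: the emissions
released by every producing region-sector anywhere in the supply chain are
assigned to the region whose final demand ultimately drove that production.

Index convention: region-major, sector-minor.  The flattened index of
(region r, sector s) is ``r * n_sectors + s``; every matrix and vector in
this module uses it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: relative tolerance for balance / conservation checks
BALANCE_RTOL = 1e-8


class MRIOError(ValueError):
    """Raised for structurally invalid input-output tables."""


@dataclass
class LinkedMRIOTable:
    """A balanced R-region x S-sector economy with domestic/foreign labels.

    Attributes
    ----------
    regions : list of str
        Region names, domestic block first.
    n_domestic : int
        Number of leading regions that are domestic (provinces).
    sectors : list of str
        Sector names, shared by every region.
    Z : ndarray, shape (R*S, R*S)
        Intermediate flows, currency units (billion US$ in the synthetic
        world).  ``Z[i, j]`` is the delivery from producer i to industry j.
    Y : ndarray, shape (R*S, R)
        Final demand of each consuming region for each product.
    x : ndarray, shape (R*S,)
        Gross output; must equal ``Z.sum(1) + Y.sum(1)``.
    """

    regions: list[str]
    n_domestic: int
    sectors: list[str]
    Z: np.ndarray
    Y: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.x = np.asarray(self.x, dtype=float)

    # -- index helpers ---------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_sectors(self) -> int:
        return len(self.sectors)

    @property
    def n_flat(self) -> int:
        return self.n_regions * self.n_sectors

    @property
    def domestic_mask(self) -> np.ndarray:
        """Boolean mask over regions, True for the domestic block."""
        m = np.zeros(self.n_regions, dtype=bool)
        m[: self.n_domestic] = True
        return m

    def flat_index(self, region: int, sector: int) -> int:
        return region * self.n_sectors + sector

    def region_of_flat(self, i: int) -> int:
        return i // self.n_sectors

    def validate(self, rtol: float = BALANCE_RTOL) -> None:
        """Check non-negativity, shapes and the row balance x = Z.1 + Y.1."""
        n, R = self.n_flat, self.n_regions
        if self.Z.shape != (n, n) or self.Y.shape != (n, R) or self.x.shape != (n,):
            raise MRIOError(
                f"inconsistent shapes: Z{self.Z.shape} Y{self.Y.shape} x{self.x.shape} "
                f"for {R} regions x {self.n_sectors} sectors"
            )
        if not 1 <= self.n_domestic <= R:
            raise MRIOError(f"n_domestic={self.n_domestic} out of range for {R} regions")
        if (self.Z < 0).any() or (self.Y < 0).any() or (self.x < 0).any():
            raise MRIOError("negative entries in Z, Y or x")
        supplied = self.Z.sum(axis=1) + self.Y.sum(axis=1)
        scale = max(self.x.max(), 1.0)
        resid = np.abs(self.x - supplied).max() / scale
        if resid > rtol:
            raise MRIOError(f"table unbalanced: max relative residual {resid:.3e}")


@dataclass
class CoefficientMatrix:
    """Technical coefficients A = Z x̂^-1 and the Leontief inverse L = (I-A)^-1."""

    A: np.ndarray
    L: np.ndarray
    spectral_radius: float


@dataclass
class EmbodiedEmissionTensor:
    """Producer-attributed emissions resolved by consuming region.

    ``values[p, r, s, c]`` is the mass (Mt) of pollutant p released by sector
    s of producing region r to satisfy the final demand of consuming region
    c, i.e. the expanded form of F̂ L Y.
    """

    pollutants: list[str]
    regions: list[str]
    n_domestic: int
    sectors: list[str]
    values: np.ndarray  # (P, R, S, R)

    def production_totals(self) -> np.ndarray:
        """Production-based totals per (pollutant, region): sum over sector+consumer."""
        return self.values.sum(axis=(2, 3))

    def consumption_totals(self) -> np.ndarray:
        """Consumption-based totals per (pollutant, region): sum over producers."""
        return self.values.sum(axis=(1, 2))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (pollutant, producer_region, sector, consumer_region, mass_Mt)."""
        P, R, S, _ = self.values.shape
        pi, ri, si, ci = np.meshgrid(
            np.arange(P), np.arange(R), np.arange(S), np.arange(R), indexing="ij"
        )
        return pd.DataFrame(
            {
                "pollutant": np.asarray(self.pollutants)[pi.ravel()],
                "producer_region": np.asarray(self.regions)[ri.ravel()],
                "sector": np.asarray(self.sectors)[si.ravel()],
                "consumer_region": np.asarray(self.regions)[ci.ravel()],
                "mass_Mt": self.values.ravel(),
            }
        )


@dataclass
class AccountingResult:
    """Production/consumption accounts and their four trade components (Mt).

    All arrays are (n_pollutants, n_regions).  For every region r::

        E_p[r] = local[r] + domestic_out[r] + foreign_out[r]
        E_c[r] = local[r] + domestic_in[r]  + foreign_in[r]

    where "domestic"/"foreign" classify the *partner* region of the flow.
    """

    pollutants: list[str]
    regions: list[str]
    n_domestic: int
    E_p: np.ndarray
    E_c: np.ndarray
    local: np.ndarray
    domestic_out: np.ndarray
    domestic_in: np.ndarray
    foreign_out: np.ndarray
    foreign_in: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, pol in enumerate(self.pollutants):
            for r, reg in enumerate(self.regions):
                rows.append(
                    {
                        "pollutant": pol,
                        "region": reg,
                        "domestic": r < self.n_domestic,
                        "E_p_Mt": self.E_p[p, r],
                        "E_c_Mt": self.E_c[p, r],
                        "local_Mt": self.local[p, r],
                        "domestic_out_Mt": self.domestic_out[p, r],
                        "domestic_in_Mt": self.domestic_in[p, r],
                        "foreign_out_Mt": self.foreign_out[p, r],
                        "foreign_in_Mt": self.foreign_in[p, r],
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def technical_coefficients(table: LinkedMRIOTable) -> CoefficientMatrix:
    """Normalize flows into coefficients and invert the Leontief system.

    A[i, j] = Z[i, j] / x[j]; columns of zero-output sectors are all zero.
    L is obtained from a dense solve of (I - A) L = I rather than an explicit
    inverse-then-multiply, for numerical stability.

    Raises
    ------
    MRIOError
        If the spectral radius of A is >= 1 (non-productive economy).
    """
    n = table.n_flat
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(table.x[None, :] > 0, table.Z / table.x[None, :], 0.0)
    if (table.x == 0).any():
        logger.warning(
            "%d zero-output sectors: their coefficient columns set to 0",
            int((table.x == 0).sum()),
        )
    rho = float(np.max(np.abs(np.linalg.eigvals(A)))) if n else 0.0
    if rho >= 1.0:
        raise MRIOError(f"non-productive economy: spectral radius {rho:.4f} >= 1")
    L = np.linalg.solve(np.eye(n) - A, np.eye(n))
    return CoefficientMatrix(A=A, L=L, spectral_radius=rho)


def embodied_emissions(
    F: np.ndarray,
    coeff: CoefficientMatrix,
    table: LinkedMRIOTable,
    pollutants: list[str],
) -> EmbodiedEmissionTensor:
    """Attribute producer emissions to final consumers: E = F̂ L Y expanded.

    Parameters
    ----------
    F : ndarray, shape (P, R*S)
        Emission intensities, Mt per currency unit, region-major flattening.
    coeff : CoefficientMatrix
        From :func:`technical_coefficients` of the same table.
    table : LinkedMRIOTable
        Supplies Y and the index labels.
    """
    F = np.asarray(F, dtype=float)
    n, R, S = table.n_flat, table.n_regions, table.n_sectors
    if F.ndim != 2 or F.shape[1] != n or coeff.L.shape != (n, n):
        raise MRIOError(f"dimension mismatch: F{F.shape}, L{coeff.L.shape}, n={n}")
    G = coeff.L @ table.Y  # (n, R): output of producer i driven by consumer c
    E = F[:, :, None] * G[None, :, :]  # (P, n, R)
    return EmbodiedEmissionTensor(
        pollutants=list(pollutants),
        regions=list(table.regions),
        n_domestic=table.n_domestic,
        sectors=list(table.sectors),
        values=E.reshape(len(pollutants), R, S, R),
    )


def accounts(tensor: EmbodiedEmissionTensor) -> AccountingResult:
    """Decompose the embodied tensor into production/consumption accounts.

    The production account of region r is its local component plus exports
    embodied in goods consumed by other domestic regions and by foreign
    regions; the consumption account symmetrically sums imports.
    """
    E = tensor.values  # (P, R, S, R)
    P, R = E.shape[0], E.shape[1]
    dom = np.zeros(R, dtype=bool)
    dom[: tensor.n_domestic] = True
    by_partner = E.sum(axis=2)  # (P, producer, consumer)

    local = np.einsum("prr->pr", by_partner)
    eye = np.eye(R, dtype=bool)
    off = np.where(~eye, 1.0, 0.0)
    dom_w = off * dom[None, :]
    for_w = off * (~dom)[None, :]
    domestic_out = np.einsum("prc,rc->pr", by_partner, dom_w)
    foreign_out = np.einsum("prc,rc->pr", by_partner, for_w)
    domestic_in = np.einsum("pcr,rc->pr", by_partner, dom_w)
    foreign_in = np.einsum("pcr,rc->pr", by_partner, for_w)

    return AccountingResult(
        pollutants=list(tensor.pollutants),
        regions=list(tensor.regions),
        n_domestic=tensor.n_domestic,
        E_p=local + domestic_out + foreign_out,
        E_c=local + domestic_in + foreign_in,
        local=local,
        domestic_out=domestic_out,
        domestic_in=domestic_in,
        foreign_out=foreign_out,
        foreign_in=foreign_in,
    )


def emission_intensity(production_emissions: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Per-unit-output emission intensity F = E / x, elementwise.

    Zero-output sectors get intensity 0 (with a logged warning); negative
    emissions are rejected.
    """
    E = np.asarray(production_emissions, dtype=float)
    x = np.asarray(x, dtype=float)
    if (E < 0).any():
        raise MRIOError("negative production emissions")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(x[None, :] > 0 if E.ndim == 2 else x > 0, E / x, 0.0)
    if (x == 0).any():
        logger.warning("zero-output sectors assigned intensity 0")
    return F


def sector_map(
    raw: pd.DataFrame,
    mapping: dict[str, dict[str, float]],
    *,
    value_col: str = "value",
    category_col: str = "category",
) -> pd.DataFrame:
    """Mass-conserving reallocation of inventory categories onto MRIO sectors.

    Parameters
    ----------
    raw : DataFrame
        Long format with a category column, a value column and any other id
        columns (region, pollutant, ...), which are preserved.
    mapping : dict
        ``{category: {sector: weight, ...}}``; each category's weights must
        sum to 1 and every category present in ``raw`` must be mapped.

    Returns
    -------
    DataFrame with the category column replaced by ``sector`` and values
    aggregated over categories mapping to the same sector.
    """
    cats = set(raw[category_col].unique())
    missing = cats - set(mapping)
    if missing:
        raise MRIOError(f"unmapped inventory categories: {sorted(missing)}")
    for cat, weights in mapping.items():
        total = sum(weights.values())
        if abs(total - 1.0) > 1e-9:
            raise MRIOError(f"weights for category {cat!r} sum to {total}, not 1")
    pieces = []
    for cat, weights in mapping.items():
        part = raw[raw[category_col] == cat]
        if part.empty:
            continue
        for sector, w in weights.items():
            piece = part.drop(columns=[category_col]).copy()
            piece[value_col] = piece[value_col] * w
            piece["sector"] = sector
            pieces.append(piece)
    out = pd.concat(pieces, ignore_index=True)
    keys = [c for c in out.columns if c != value_col]
    return out.groupby(keys, as_index=False)[value_col].sum()


def link_tables(
    domestic: LinkedMRIOTable,
    foreign: LinkedMRIOTable,
    exports: np.ndarray,
    imports: np.ndarray,
) -> LinkedMRIOTable:
    """Couple a domestic MRIO with a foreign IO table via bilateral trade.

    Each bilateral export flow (producer region-sector -> partner region) is
    split into an intermediate-delivery part (into the partner's industries)
    and a final-demand part, proportionally to the partner's own
    intermediate-vs-final absorption shares for that product, then inserted
    into the off-diagonal blocks.  By construction the inserted IDM + FDM
    re-sum exactly to the given export/import matrices.  Gross output is
    recomputed as the row balance of the coupled table.

    Parameters
    ----------
    domestic, foreign : LinkedMRIOTable
        Stand-alone balanced tables (the ``n_domestic`` label of ``foreign``
        is ignored; all its regions are treated as foreign).
    exports : ndarray, shape (R_d*S, R_f)
        Exports from each domestic region-sector to each foreign region.
    imports : ndarray, shape (R_f*S, R_d)
        Imports of each domestic region from each foreign region-sector.
    """
    if domestic.sectors != foreign.sectors:
        raise MRIOError("sector lists must match after mapping")
    S = domestic.n_sectors
    Rd, Rf = domestic.n_regions, foreign.n_regions
    nd, nf = Rd * S, Rf * S
    exports = np.asarray(exports, dtype=float)
    imports = np.asarray(imports, dtype=float)
    if exports.shape != (nd, Rf) or imports.shape != (nf, Rd):
        raise MRIOError(
            f"trade matrices must be ({nd},{Rf}) and ({nf},{Rd}); "
            f"got {exports.shape} and {imports.shape}"
        )
    if (exports < 0).any() or (imports < 0).any():
        raise MRIOError("trade matrices must be nonnegative")

    n = nd + nf
    Z = np.zeros((n, n))
    Y = np.zeros((nd + nf, Rd + Rf))
    Z[:nd, :nd] = domestic.Z
    Z[nd:, nd:] = foreign.Z
    Y[:nd, :Rd] = domestic.Y
    Y[nd:, Rd:] = foreign.Y

    _allocate_trade(Z, Y, exports, domestic_rows=True, dest=foreign, S=S, nd=nd, Rd=Rd)
    _allocate_trade(Z, Y, imports, domestic_rows=False, dest=domestic, S=S, nd=nd, Rd=Rd)

    x = Z.sum(axis=1) + Y.sum(axis=1)
    table = LinkedMRIOTable(
        regions=list(domestic.regions) + list(foreign.regions),
        n_domestic=Rd,
        sectors=list(domestic.sectors),
        Z=Z,
        Y=Y,
        x=x,
    )
    table.validate()
    # fail fast if the coupled economy stopped being productive
    technical_coefficients(table)
    return table


def _allocate_trade(Z, Y, trade, *, domestic_rows, dest, S, nd, Rd):
    """Insert bilateral flows split by the destination's absorption shares."""
    n_rows, n_dest = trade.shape
    for j in range(n_dest):
        # destination region's internal absorption of each product sector
        dj0 = j * S
        inter = dest.Z[dj0 : dj0 + S, dj0 : dj0 + S]  # product s -> industries
        final = dest.Y[dj0 : dj0 + S, j]
        inter_tot = inter.sum(axis=1)
        denom = inter_tot + final
        for i in range(n_rows):
            e = trade[i, j]
            if e == 0:
                continue
            s = i % S
            if denom[s] <= 0:
                if e > 0 and final.sum() + inter.sum() <= 0:
                    raise MRIOError(
                        f"infeasible link: destination region {j} absorbs nothing "
                        f"of sector {s} but receives {e}"
                    )
                idm_share = 0.0  # no internal use pattern: treat as final demand
            else:
                idm_share = inter_tot[s] / denom[s]
            idm = e * idm_share
            fdm = e - idm
            if domestic_rows:
                row, col0, ycol = i, nd + dj0, Rd + j
            else:
                row, col0, ycol = nd + i, dj0, j
            if idm > 0:
                pattern = inter[s] / inter[s].sum()
                Z[row, col0 : col0 + S] += idm * pattern
            Y[row, ycol] += fdm
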
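"""Per-site hydration thermodynamics: Etot, TStot, dH, dG and the Kss displacement score.

Solvent-mapping (GIST + hydration-site analysis of a restrained explicit-water
MD trajectory) summarizes each localized water site by its occupancy, its
solute-water interaction energy ``E_sw``, its *half* water-water interaction
energy ``E_ww`` (the 1/2 factor prevents double counting of pair energies),
and single-body translational/orientational entropy terms that are already
``T*dS`` products in kcal/mol.  This module consumes such per-site tables and
derives:

    Etot  = E_sw + E_ww
    TStot = TS_trans + TS_orient
    dH    = E_sw + 2*(E_ww - E_bulk)          (per-water excess enthalpy)
    dG    = dH - TStot
    Kss   = occupancy * (Etot - E_bulk)       (displacement score)

``E_bulk`` is the mean per-water interaction energy of the bulk water model,
-9.565 kcal/mol/water for TIP3P.  A site whose total water interaction energy
is worse than bulk (Etot > E_bulk) has Kss > 0: an "unhappy", easily displaced
water, attractive for ligand design.  Kss < 0 marks "happy" water that is hard
to displace; the lower the score, the harder the displacement.

A 28-site reference table for the apo human PD-L1 surface (100 ns restrained
TIP3P simulation, CPPTRAJ HSA output) ships with the package; see
:func:`load_reference_sites`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "HydrationSite",
    "ScoredSite",
    "BulkReference",
    "TIP3P_E_BULK",
    "total_energy",
    "total_entropy",
    "enthalpy",
    "free_energy",
    "kss",
    "classify_and_rank",
    "score_table",
    "read_sites_csv",
    "read_hsa_summary",
    "load_reference_sites",
    "write_pseudoatom_pdb",
]

TIP3P_E_BULK = -9.565  # kcal/mol per water, TIP3P mean interaction energy


@dataclass(frozen=True)
class HydrationSite:
    """One water site: occupancy, energies and TdS entropy terms (kcal/mol)."""

    site_id: str
    occupancy: float
    e_sw: float
    e_ww: float  # half-counted water-water energy
    ts_trans: float
    ts_orient: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"{self.site_id}: occupancy must be in [0, 1], got {self.occupancy}"
            )
        for name in ("e_sw", "e_ww", "ts_trans", "ts_orient"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{self.site_id}: {name} must be finite")


@dataclass(frozen=True)
class BulkReference:
    """Bulk-water energy reference; temperature is implicit in the TdS inputs."""

    e_bulk: float = TIP3P_E_BULK

    def __post_init__(self) -> None:
        if not (math.isfinite(self.e_bulk) and self.e_bulk < 0):
            raise ValueError(f"e_bulk must be a negative energy, got {self.e_bulk}")


@dataclass(frozen=True)
class ScoredSite(HydrationSite):
    """Hydration site with derived thermodynamic scores attached."""

    e_tot: float = 0.0
    ts_tot: float = 0.0
    delta_h: float = 0.0
    delta_g: float = 0.0
    kss: float = 0.0
    favorability: str = "unfavorable"


def total_energy(site: HydrationSite) -> float:
    """Total water interaction energy Etot = E_sw + E_ww."""
    return site.e_sw + site.e_ww


def total_entropy(site: HydrationSite) -> float:
    """Total entropy term TStot = TS_trans + TS_orient."""
    return site.ts_trans + site.ts_orient


def enthalpy(site: HydrationSite, bulk: BulkReference = BulkReference()) -> float:
    """Per-water excess enthalpy dH = E_sw + 2*(E_ww - E_bulk).

    Zero for a bulk-like site (no solute contact, E_ww equal to the bulk
    reference).
    """
    return site.e_sw + 2.0 * (site.e_ww - bulk.e_bulk)


def free_energy(site: HydrationSite, bulk: BulkReference = BulkReference()) -> float:
    """Free energy dG = dH - TStot; high values mark easy-to-displace water."""
    return enthalpy(site, bulk) - total_entropy(site)


def kss(site: HydrationSite, bulk: BulkReference = BulkReference()) -> float:
    """Displacement score Kss = occupancy * (E_sw + E_ww - E_bulk).

    Linear in occupancy; positive when the site's total energy is worse than
    bulk (displaceable, "unhappy" water), negative when better (tightly held).
    """
    return site.occupancy * (total_energy(site) - bulk.e_bulk)


def _score_one(site: HydrationSite, bulk: BulkReference) -> ScoredSite:
    k = kss(site, bulk)
    return ScoredSite(
        site_id=site.site_id,
        occupancy=site.occupancy,
        e_sw=site.e_sw,
        e_ww=site.e_ww,
        ts_trans=site.ts_trans,
        ts_orient=site.ts_orient,
        e_tot=total_energy(site),
        ts_tot=total_entropy(site),
        delta_h=enthalpy(site, bulk),
        delta_g=free_energy(site, bulk),
        kss=k,
        favorability="favorable" if k < 0 else "unfavorable",
    )


def classify_and_rank(
    sites: Sequence[HydrationSite], bulk: BulkReference = BulkReference()
) -> list[ScoredSite]:
    """Score every site and sort by Kss descending (most displaceable first).

    Kss exactly zero is classified *unfavorable* (only strictly negative
    scores mark hard-to-displace water).
    """
    if not sites:
        raise ValueError("need at least one hydration site")
    scored = [_score_one(s, bulk) for s in sites]
    return sorted(scored, key=lambda s: (-s.kss, s.site_id))


def score_table(
    df: pd.DataFrame, bulk: BulkReference = BulkReference()
) -> pd.DataFrame:
    """Vectorized scoring of a site table; returns a Kss-descending DataFrame.

    Expects columns ``site_id, occupancy, e_sw, e_ww, ts_trans, ts_orient``
    (extra columns such as coordinates pass through untouched) and appends
    ``e_tot, ts_tot, delta_h, delta_g, kss, favorability``.
    """
    sites = [
        HydrationSite(
            site_id=str(r.site_id),
            occupancy=float(r.occupancy),
            e_sw=float(r.e_sw),
            e_ww=float(r.e_ww),
            ts_trans=float(r.ts_trans),
            ts_orient=float(r.ts_orient),
        )
        for r in df.itertuples()
    ]
    scored = classify_and_rank(sites, bulk)
    out = pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "occupancy": s.occupancy,
                "e_sw": s.e_sw,
                "e_ww": s.e_ww,
                "e_tot": s.e_tot,
                "ts_trans": s.ts_trans,
                "ts_orient": s.ts_orient,
                "ts_tot": s.ts_tot,
                "delta_h": s.delta_h,
                "delta_g": s.delta_g,
                "kss": s.kss,
                "favorability": s.favorability,
            }
            for s in scored
        ]
    )
    extra = [c for c in df.columns if c not in out.columns]
    if extra:
        out = out.merge(df[["site_id", *extra]].astype({"site_id": str}), on="site_id")
    return out


def read_sites_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-site CSV with the canonical column names."""
    df = pd.read_csv(path)
    required = {"site_id", "occupancy", "e_sw", "e_ww", "ts_trans", "ts_orient"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hydration table missing columns: {sorted(missing)}")
    return df


# column aliases for CPPTRAJ hydration-site-analysis summary output
_HSA_ALIASES = {
    "site_id": ("site_id", "index", "site", "cluster"),
    "occupancy": ("occupancy", "occ", "solute_occupancy"),
    "e_sw": ("e_sw", "esw", "eswtot", "e_solute_water"),
    "e_ww": ("e_ww", "eww", "ewwtot", "e_water_water"),
    "ts_trans": ("ts_trans", "tssw_trans", "ts_tr", "tstrans"),
    "ts_orient": ("ts_orient", "tssw_orient", "ts_or", "tsorient"),
}


def read_hsa_summary(path: str | Path) -> pd.DataFrame:
    """Read a CPPTRAJ HSA-style summary (whitespace- or comma-delimited).

    Column names are matched case-insensitively against common HSA spellings
    (Esw/Eww/TSsw_trans/TSsw_orient ...) and normalized to the canonical
    schema used throughout this module.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    lower = {c.lower().strip().lstrip("#"): c for c in df.columns}
    rename = {}
    for canon, aliases in _HSA_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                rename[lower[alias]] = canon
                break
        else:
            raise ValueError(
                f"could not find a column for {canon!r} in {sorted(df.columns)}"
            )
    out = df.rename(columns=rename)[list(_HSA_ALIASES)]
    out["site_id"] = out["site_id"].astype(str)
    return out


def load_reference_sites() -> pd.DataFrame:
    """The packaged 28-site apo-PD-L1 hydration-site table.

    Per-site HSA summary (occupancy, E_sw, half-counted E_ww, TdS terms) from
    a 100 ns restrained TIP3P simulation of the free PD-L1 protein, together
    with the published Etot/TStot/Kss columns (``e_tot``, ``ts_tot``,
    ``kss_score``) for regression checks.  Inputs are printed to two decimals,
    so recomputed quantities match the reference columns only to that
    rounding.
    """
    with resources.files("fwsolv.data").joinpath("pdl1_hydration_sites.csv").open() as fh:
        return pd.read_csv(fh)


def write_pseudoatom_pdb(scored: pd.DataFrame, path: str | Path) -> None:
    """Write one oxygen pseudo-atom per site, B-factor = Kss.

    Requires ``x, y, z`` coordinate columns on the scored table; useful for
    coloring sites by displaceability in a molecular viewer.
    """
    for col in ("x", "y", "z"):
        if col not in scored.columns:
            raise ValueError("pseudo-atom export needs x, y, z columns")
    lines = []
    for i, row in enumerate(scored.itertuples(), start=1):
        lines.append(
            f"HETATM{i:5d}  O   HOH A{i:4d}    "
            f"{row.x:8.3f}{row.y:8.3f}{row.z:8.3f}{row.occupancy:6.2f}{row.kss:6.2f}"
            f"          O"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
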
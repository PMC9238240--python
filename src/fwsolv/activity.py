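"""Activity-table ingestion: read, clean, deduplicate and log-transform IC50 data.

The QSAR stages downstream consume a *curated* table with one row per unique
compound and potency on the pIC50 scale.  Raw tables (hand-built CSVs or
BindingDB-style TSV exports) frequently contain the same compound several
times, under different identifiers, with independently measured IC50 values;
those replicate measurements are averaged on the nanomolar scale before the
log transform, and structural identity (canonical SMILES) — not the id
string — decides what counts as "the same compound".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityRecord",
    "CuratedDataset",
    "ic50_to_pic50",
    "pic50_to_ic50",
    "aggregate_duplicates",
    "read_activity_table",
    "curate",
]


@dataclass(frozen=True)
class ActivityRecord:
    """One ligand's structure plus a measured potency (IC50, nanomolar)."""

    ligand_id: str
    smiles: str
    ic50_nM: float

    def __post_init__(self) -> None:
        if not (isinstance(self.ic50_nM, (int, float)) and math.isfinite(self.ic50_nM)):
            raise ValueError(
                f"ic50_nM must be a finite number in nanomolar units, got {self.ic50_nM!r}"
            )
        if self.ic50_nM <= 0:
            raise ValueError(
                f"ic50_nM must be > 0 (a concentration in nM), got {self.ic50_nM!r}"
            )


@dataclass(frozen=True)
class CuratedDataset:
    """Deduplicated activity table on the pIC50 scale.

    ``records`` is a DataFrame with columns ``ligand_id``, ``smiles`` (canonical),
    ``pic50`` and ``n_source_records``; one row per unique structure.
    ``n_skipped`` counts input rows dropped for unparseable SMILES.
    """

    records: pd.DataFrame
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def ic50_to_pic50(ic50_nM: float) -> float:
    """Convert an IC50 in nanomolar to pIC50 = -log10(IC50 in molar).

    Since 1 nM = 1e-9 M this is ``9 - log10(ic50_nM)``; 1000 nM maps to 6.0.
    """
    if not (isinstance(ic50_nM, (int, float)) and math.isfinite(ic50_nM)):
        raise ValueError(
            f"IC50 must be a finite concentration in nM, got {ic50_nM!r}"
        )
    if ic50_nM <= 0:
        raise ValueError(
            f"IC50 must be positive (a concentration in nM); got {ic50_nM!r}. "
            "pIC50 = 9 - log10(IC50/nM) is undefined otherwise."
        )
    return 9.0 - math.log10(ic50_nM)


def pic50_to_ic50(pic50: float) -> float:
    """Inverse of :func:`ic50_to_pic50`: pIC50 back to IC50 in nanomolar."""
    return 10.0 ** (9.0 - pic50)


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES, or None if the input does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def aggregate_duplicates(records: Iterable[ActivityRecord]) -> CuratedDataset:
    """Collapse replicate measurements into one row per unique structure.

    Identity is the canonical structure, so one compound listed under two ids
    collapses to a single row.  Replicate IC50 values are averaged
    arithmetically on the nM scale and converted to pIC50 *after* averaging.
    Rows whose SMILES fails to parse are skipped, logged, and counted in
    ``n_skipped``.
    """
    rows = []
    n_skipped = 0
    for rec in records:
        canon = canonical_smiles(rec.smiles)
        if canon is None:
            logger.warning("skipping %s: unparseable SMILES %r", rec.ligand_id, rec.smiles)
            n_skipped += 1
            continue
        rows.append((canon, rec.ligand_id, rec.ic50_nM))
    if n_skipped:
        logger.info("aggregate_duplicates: skipped %d unparseable rows", n_skipped)

    by_structure: dict[str, list[tuple[str, float]]] = {}
    for canon, lig_id, ic50 in rows:
        by_structure.setdefault(canon, []).append((lig_id, ic50))

    out = []
    for canon in sorted(by_structure):
        entries = by_structure[canon]
        mean_ic50 = sum(v for _, v in entries) / len(entries)
        out.append(
            {
                "ligand_id": entries[0][0],  # first id seen for this structure
                "smiles": canon,
                "pic50": ic50_to_pic50(mean_ic50),
                "n_source_records": len(entries),
            }
        )
    df = pd.DataFrame(out, columns=["ligand_id", "smiles", "pic50", "n_source_records"])
    return CuratedDataset(records=df, n_skipped=n_skipped)


def read_activity_table(path: str | Path) -> list[ActivityRecord]:
    """Read a raw activity table (CSV, or TSV as in BindingDB exports).

    Requires columns ``ligand_id``, ``smiles``, ``ic50_nM``; the delimiter is
    sniffed so both comma- and tab-separated files work.  Rows with missing or
    non-positive IC50 (including censored values that fail to parse as numbers)
    are dropped with a log message.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"ligand_id", "smiles", "ic50_nM"} - set(df.columns)
    if missing:
        raise ValueError(f"activity table missing required columns: {sorted(missing)}")
    records = []
    n_bad = 0
    for _, row in df.iterrows():
        try:
            ic50 = float(row["ic50_nM"])
            rec = ActivityRecord(str(row["ligand_id"]), str(row["smiles"]), ic50)
        except (TypeError, ValueError):
            n_bad += 1
            continue
        records.append(rec)
    if n_bad:
        logger.warning("read_activity_table: dropped %d rows with missing/censored/non-positive IC50", n_bad)
    return records


def curate(path: str | Path) -> CuratedDataset:
    """Read + aggregate in one step (raw table file -> curated dataset)."""
    return aggregate_duplicates(read_activity_table(path))
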
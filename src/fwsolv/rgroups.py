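"""R-group decomposition against a numbered core scaffold, and the one-hot design matrix.

A congeneric series is expressed as a shared core with S numbered attachment
points (``[*:1]`` ... ``[*:S]`` dummy atoms in the core SMILES) plus one
substituent per site.  Unsubstituted positions are encoded as an explicit
hydrogen substituent — "no substituent" is itself a level that can carry a
Free-Wilson coefficient.

When the core matches a molecule in several symmetry-equivalent ways, all
substructure matches are enumerated and the canonical assignment is the
lexicographically smallest (site -> canonical substituent SMILES) mapping, so
decomposition is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "CoreScaffold",
    "RGroupAssignment",
    "DesignMatrix",
    "decompose",
    "build_design_matrix",
    "attach_groups",
    "load_scaffold",
]

_MAX_CORE_MATCHES = 5000


@dataclass(frozen=True)
class CoreScaffold:
    """Core structure with numbered attachment points.

    ``core`` is a SMILES string containing dummy atoms ``[*:k]`` for sites
    k = 1..S.  ``site_labels`` optionally names the sites (defaults R1..RS).
    """

    core: str
    site_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        mol = Chem.MolFromSmiles(self.core)
        if mol is None:
            raise ValueError(f"core scaffold SMILES does not parse: {self.core!r}")
        sites = sorted(
            a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomicNum() == 0
        )
        if not sites:
            raise ValueError("core scaffold has no numbered attachment points [*:k]")
        if sites != list(range(1, len(sites) + 1)):
            raise ValueError(
                f"attachment points must be uniquely numbered 1..S, got {sites}"
            )
        if self.site_labels and len(self.site_labels) != len(sites):
            raise ValueError(
                f"{len(self.site_labels)} labels for {len(sites)} sites"
            )
        if not self.site_labels:
            object.__setattr__(
                self, "site_labels", tuple(f"R{k}" for k in sites)
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    @property
    def sites(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_sites + 1))

    def query_mol(self) -> Chem.Mol:
        """Core as a substructure query whose dummies match any atom (incl. H)."""
        mol = Chem.MolFromSmiles(self.core)
        params = Chem.AdjustQueryParameters.NoAdjustments()
        params.makeDummiesQueries = True
        return Chem.AdjustQueryProperties(mol, params)


@dataclass(frozen=True)
class RGroupAssignment:
    """One ligand expressed as core + per-site substituents.

    ``groups`` maps site index -> attachment-anchored canonical substituent
    SMILES (a single ``*`` dummy marks the bond to the core; hydrogen is the
    explicit substituent ``*[H]``).  ``matched`` is False when the core is not
    a clean substructure of the molecule; ``reason`` then says why.
    """

    ligand_id: str
    groups: Mapping[int, str] = field(default_factory=dict)
    matched: bool = True
    reason: str = ""


@dataclass
class DesignMatrix:
    """One-hot (site, substituent) design matrix for a decomposed series.

    Every row has exactly S ones — one per site — and ``column_index`` lists
    the (site, substituent SMILES) key of each column in a deterministic
    (sorted) order.
    """

    X: np.ndarray
    column_index: list[tuple[int, str]]
    ligand_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def column_names(self) -> list[str]:
        return [f"R{site}:{sub}" for site, sub in self.column_index]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.X, index=self.ligand_ids, columns=self.column_names()
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="ligand_id")

    def to_mtx(self, path: str | Path) -> None:
        from scipy import io as sio
        from scipy import sparse

        sio.mmwrite(str(path), sparse.csr_matrix(self.X))


def _substituent_smiles(mol: Chem.Mol, comp: set[int], root: int, bond_type) -> str:
    """Canonical SMILES of the substituent atoms ``comp``, anchored by one dummy."""
    rw = Chem.RWMol()
    amap: dict[int, int] = {}
    for idx in sorted(comp):
        old = mol.GetAtomWithIdx(idx)
        atom = Chem.Atom(old.GetAtomicNum())
        atom.SetFormalCharge(old.GetFormalCharge())
        atom.SetIsAromatic(old.GetIsAromatic())
        atom.SetNumExplicitHs(old.GetNumExplicitHs())
        atom.SetNoImplicit(old.GetNoImplicit())
        if old.GetIsotope():
            atom.SetIsotope(old.GetIsotope())
        amap[idx] = rw.AddAtom(atom)
    seen_bonds: set[int] = set()
    for idx in comp:
        for bond in mol.GetAtomWithIdx(idx).GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i in comp and j in comp and bond.GetIdx() not in seen_bonds:
                seen_bonds.add(bond.GetIdx())
                rw.AddBond(amap[i], amap[j], bond.GetBondType())
    anchor = rw.AddAtom(Chem.Atom(0))
    rw.AddBond(amap[root], anchor, bond_type)
    frag = rw.GetMol()
    Chem.SanitizeMol(frag)
    frag = Chem.RemoveHs(frag)
    return Chem.MolToSmiles(frag)


def decompose(
    smiles: str, scaffold: CoreScaffold, ligand_id: str | None = None
) -> RGroupAssignment:
    """Decompose a molecule into per-site substituents on the core scaffold.

    All substructure matches of the core are enumerated; matches where a core
    atom carries an off-site substituent, or where one substituent bridges two
    attachment points, are rejected.  Among the surviving symmetry-equivalent
    assignments the lexicographically smallest (by per-site canonical
    substituent SMILES) is returned.
    """
    lig = ligand_id if ligand_id is not None else smiles
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return RGroupAssignment(lig, matched=False, reason="unparseable SMILES")
    molH = Chem.AddHs(mol)
    query = scaffold.query_mol()
    core_mol = Chem.MolFromSmiles(scaffold.core)

    dummy_q = {
        a.GetAtomMapNum(): a.GetIdx()
        for a in core_mol.GetAtoms()
        if a.GetAtomicNum() == 0
    }
    heavy_q = [a.GetIdx() for a in core_mol.GetAtoms() if a.GetAtomicNum() != 0]

    matches = molH.GetSubstructMatches(
        query, uniquify=False, maxMatches=_MAX_CORE_MATCHES
    )
    if not matches:
        return RGroupAssignment(lig, matched=False, reason="core not a substructure")

    candidates: set[tuple[str, ...]] = set()
    reject_reason = "no clean core match"
    for match in matches:
        core_t = {match[q] for q in heavy_q}
        roots = {site: match[q] for site, q in dummy_q.items()}
        root_set = set(roots.values())
        # a core atom may bond outside the match only through a numbered site;
        # its own (explicit) hydrogens are part of the core, not substituents
        ok = True
        core_hydrogens: set[int] = set()
        for t in core_t:
            for nbr in molH.GetAtomWithIdx(t).GetNeighbors():
                n = nbr.GetIdx()
                if n in core_t or n in root_set:
                    continue
                if nbr.GetAtomicNum() == 1:
                    core_hydrogens.add(n)
                    continue
                ok = False
                reject_reason = "core bears a substituent at an unnumbered position"
                break
            if not ok:
                break
        if not ok:
            continue
        # grow each substituent component; it must stay off the core and off
        # every other site's component (no bridging substituents)
        comps: dict[int, set[int]] = {}
        for site, root in sorted(roots.items()):
            comp = {root}
            stack = [root]
            while stack:
                cur = stack.pop()
                for nbr in molH.GetAtomWithIdx(cur).GetNeighbors():
                    n = nbr.GetIdx()
                    if n in core_t or n in comp:
                        continue
                    comp.add(n)
                    stack.append(n)
            comps[site] = comp
        flat: list[int] = []
        for comp in comps.values():
            flat.extend(comp)
        if len(flat) != len(set(flat)):
            ok = False
            reject_reason = "a substituent bridges two attachment points"
        if not ok:
            continue
        # every molecule atom must be accounted for (core + substituents)
        covered = core_t | core_hydrogens | set(flat)
        if len(covered) != molH.GetNumAtoms():
            reject_reason = "molecule has atoms outside core and substituents"
            continue
        assignment = []
        for site in scaffold.sites:
            root = roots[site]
            bond = molH.GetBondBetweenAtoms(
                root,
                next(
                    n.GetIdx()
                    for n in molH.GetAtomWithIdx(root).GetNeighbors()
                    if n.GetIdx() in core_t
                ),
            )
            assignment.append(
                _substituent_smiles(molH, comps[site], root, bond.GetBondType())
            )
        candidates.add(tuple(assignment))

    if not candidates:
        return RGroupAssignment(lig, matched=False, reason=reject_reason)
    best = min(candidates)
    return RGroupAssignment(
        lig, groups={s: g for s, g in zip(scaffold.sites, best)}, matched=True
    )


def build_design_matrix(assignments: Sequence[RGroupAssignment]) -> DesignMatrix:
    """One-hot encode matched assignments: one column per observed (site, group).

    Unmatched assignments are excluded.  Column order is sorted by
    (site, substituent SMILES) so identical inputs in any row order produce an
    identical column index.
    """
    matched = [a for a in assignments if a.matched]
    if not matched:
        raise ValueError("no matched assignments to encode")
    columns = sorted({(s, g) for a in matched for s, g in a.groups.items()})
    col_pos = {key: j for j, key in enumerate(columns)}
    X = np.zeros((len(matched), len(columns)), dtype=np.int8)
    for i, a in enumerate(matched):
        for s, g in a.groups.items():
            X[i, col_pos[(s, g)]] = 1
    return DesignMatrix(
        X=X, column_index=columns, ligand_ids=[a.ligand_id for a in matched]
    )


def attach_groups(scaffold: CoreScaffold, groups: Mapping[int, str]) -> str | None:
    """Reattach one substituent per site to the core; canonical SMILES or None.

    The inverse of :func:`decompose`.  Returns None when the combination is
    chemically invalid (sanitization fails on the assembled molecule).
    """
    core = Chem.MolFromSmiles(scaffold.core)
    combined = core
    for site in scaffold.sites:
        frag = Chem.MolFromSmiles(groups[site])
        if frag is None:
            return None
        dummies = [a for a in frag.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            return None
        frag = Chem.RWMol(frag)
        frag.GetAtomWithIdx(dummies[0].GetIdx()).SetAtomMapNum(site)
        combined = Chem.CombineMols(combined, frag.GetMol())
    try:
        zipped = Chem.molzip(combined)
        zipped = Chem.RemoveHs(zipped)
        Chem.SanitizeMol(zipped)
    except Exception:
        return None
    return Chem.MolToSmiles(zipped)


def rgroup_table(
    assignments: Sequence[RGroupAssignment], scaffold: CoreScaffold
) -> pd.DataFrame:
    """Per-ligand R-group table (ligand_id, R1..RS substituent SMILES)."""
    rows = []
    for a in assignments:
        if not a.matched:
            continue
        row = {"ligand_id": a.ligand_id}
        for site, label in zip(scaffold.sites, scaffold.site_labels):
            row[label] = a.groups[site]
        rows.append(row)
    return pd.DataFrame(rows)


def load_scaffold(path: str | Path) -> CoreScaffold:
    """Load a scaffold from a YAML config with keys ``core`` and ``site_labels``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return CoreScaffold(
        core=cfg["core"], site_labels=tuple(cfg.get("site_labels") or ())
    )
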
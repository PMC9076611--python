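"""Nucleotide-protein distance-of-closest-approach analysis.

Given a coordinate model (PDB or mmCIF, e.g. a termination-complex
structure such as 5LZU), compute the minimum all-atom distance between a
called nucleotide and a protein chain (typically eRF1) and classify sites
into proximity bands: < 10 Å, < 16 Å, >= 40 Å, or intermediate.

Residue numbering follows the coordinate file's author numbering; mapping
between species-specific rRNA numberings is the caller's responsibility.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ProximityResult",
    "StructureModel",
    "classify_proximity",
    "load_structure",
    "min_distance",
    "parse_selector",
]

_SELECTOR_RE = re.compile(r"^(?P<chain>[^:]+):(?P<start>-?\d+)(?:-(?P<end>-?\d+))?$")


@dataclass
class StructureModel:
    """Flat atom table (chain, seqid, resname, atom, element, x, y, z)."""

    atoms: pd.DataFrame
    name: str = ""

    def select(self, chain: str, resid_start: int | None = None, resid_end: int | None = None) -> np.ndarray:
        """Coordinates of a chain, optionally restricted to a residue range
        (inclusive, author numbering)."""
        mask = self.atoms["chain"] == chain
        if resid_start is not None:
            end = resid_end if resid_end is not None else resid_start
            mask &= self.atoms["seqid"].between(resid_start, end)
        return self.atoms.loc[mask, ["x", "y", "z"]].to_numpy(dtype=float)

    def representative(self, chain: str, resid_start: int | None = None, resid_end: int | None = None) -> np.ndarray:
        """Representative-atom coordinates (C1' for nucleotides, CA for
        amino acids) for the same selection."""
        mask = self.atoms["chain"] == chain
        if resid_start is not None:
            end = resid_end if resid_end is not None else resid_start
            mask &= self.atoms["seqid"].between(resid_start, end)
        mask &= self.atoms["atom"].isin(["C1'", "CA"])
        return self.atoms.loc[mask, ["x", "y", "z"]].to_numpy(dtype=float)


def load_structure(path, include_hetero: bool = False) -> StructureModel:
    """Load a PDB or mmCIF file into a flat atom table.

    Waters are always dropped; other heteroatoms (ligands, ions) are
    dropped unless ``include_hetero``. Raises ValueError with parser
    context for unreadable files.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    rows = []
    model = st[0]
    for chain in model:
        for residue in chain:
            if residue.is_water():
                continue
            if residue.het_flag == "H" and not include_hetero:
                continue
            for atom in residue:
                rows.append(
                    (
                        chain.name,
                        residue.seqid.num,
                        residue.name,
                        atom.name,
                        atom.element.name,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                    )
                )
    if not rows:
        raise ValueError(f"structure file {path} contains no usable atoms")
    atoms = pd.DataFrame(rows, columns=["chain", "seqid", "resname", "atom", "element", "x", "y", "z"])
    if not np.isfinite(atoms[["x", "y", "z"]].to_numpy()).all():
        raise ValueError(f"non-finite coordinates in {path}")
    return StructureModel(atoms=atoms, name=st.name)


def parse_selector(selector: str) -> tuple[str, int, int]:
    """Parse ``chain:resid`` or ``chain:start-end`` into (chain, start, end)."""
    m = _SELECTOR_RE.match(selector)
    if not m:
        raise ValueError(f"bad selector {selector!r}; expected 'chain:resid[-resid]'")
    start = int(m.group("start"))
    end = int(m.group("end")) if m.group("end") else start
    return m.group("chain"), start, end


def min_distance(
    model: StructureModel,
    nucleotide_selector: str,
    target_selector: str,
    mode: str = "all_atom",
) -> float:
    """Minimum Euclidean distance (Å) between two selections.

    ``mode="all_atom"`` (default) takes the minimum over every atom pair;
    ``mode="representative"`` uses C1'/CA atoms only. Raises on empty
    selections, naming the selector.
    """
    chain_a, start_a, end_a = parse_selector(nucleotide_selector)
    chain_b, start_b, end_b = (
        parse_selector(target_selector)
        if ":" in target_selector
        else (target_selector, None, None)
    )
    pick = model.select if mode == "all_atom" else model.representative
    a = pick(chain_a, start_a, end_a)
    b = pick(chain_b, start_b, end_b)
    if a.size == 0:
        raise ValueError(f"empty selection for {nucleotide_selector!r}")
    if b.size == 0:
        raise ValueError(f"empty selection for {target_selector!r}")
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return float(np.min(d))


@dataclass
class ProximityResult:
    nucleotide: str
    min_distance: float
    band: str


def classify_proximity(
    distances: dict[str, float] | pd.Series,
    thresholds: tuple[float, float, float] = (10.0, 16.0, 40.0),
) -> pd.DataFrame:
    """Assign proximity bands to distances of closest approach.

    Half-open bands: d < 10 -> proximal_10; 10 <= d < 16 -> proximal_16;
    d >= 40 -> distal_40plus; otherwise intermediate.
    """
    t10, t16, t40 = thresholds
    items = distances.items() if hasattr(distances, "items") else distances
    rows = []
    for nucleotide, d in items:
        if d < 0:
            raise ValueError(f"negative distance for {nucleotide}")
        if d < t10:
            band = "proximal_10"
        elif d < t16:
            band = "proximal_16"
        elif d >= t40:
            band = "distal_40plus"
        else:
            band = "intermediate"
        rows.append((nucleotide, float(d), band))
    return pd.DataFrame(rows, columns=["nucleotide", "min_distance_A", "band"])
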
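"""Experimental restraints: NOE/ROE distance bounds and per-medium RDC tables.

Table formats (documented external interface; all distances Angstrom, all
couplings Hz; atom labels are element symbol + 1-based atom index):

NOE table -- one restraint per line, ``#`` comments allowed::

    # group_i   group_j    r_mean            (bounds become r_mean -/+ 10%)
    H7          H9         2.50
    H7          H9         2.25  2.75        # explicit lower/upper instead
    H7          @C3        3.00              # @C3 = all H bonded to atom C3
    H7          H9/H10     2.80              # explicit multi-proton group

Groups with more than one proton are back-calculated as <r^-6>-averaged
distances (unassigned diastereotopic protons, methyl groups, equivalent
aromatic protons).

RDC table -- one file per alignment medium, one C-H coupling per line::

    C2   H8    D=4.0            # 1D_CH directly
    C2   H8    T=148.0 J=140.0  # 1T = 1J + 2 1D  =>  D = (T - J)/2
    C5   H11   H12   D=7.2      # two protons: methylene sum D(Ha)+D(Hb)
    C2   H8    4.0              # bare number = D
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .molgraph import ChiralRestraint, MoleculeGraph


class RestraintError(ValueError):
    pass


@dataclass(frozen=True)
class NoeRestraint:
    group_i: tuple[int, ...]
    group_j: tuple[int, ...]
    r_lower: float
    r_upper: float
    averaging: str = "none"  # "r6" for multi-proton groups
    label: str = ""

    def __post_init__(self):
        if not self.group_i or not self.group_j:
            raise RestraintError("NOE groups must be non-empty")
        if set(self.group_i) & set(self.group_j):
            raise RestraintError("NOE groups must be disjoint")
        if not 0 < self.r_lower < self.r_upper:
            raise RestraintError(
                f"invalid NOE bounds [{self.r_lower}, {self.r_upper}]"
            )


@dataclass(frozen=True)
class RdcRestraint:
    medium: int
    atom_c: int
    atom_h: tuple[int, ...]  # one index, or two for a methylene sum
    d_exp: float
    mode: str = "single"  # single | methylene_sum


@dataclass
class RestraintSet:
    noes: list[NoeRestraint] = field(default_factory=list)
    rdcs: list[RdcRestraint] = field(default_factory=list)
    chirals: list[ChiralRestraint] = field(default_factory=list)

    @property
    def n_media(self) -> int:
        return 1 + max((r.medium for r in self.rdcs), default=-1)

    def validate(self, graph: MoleculeGraph) -> None:
        n = graph.n_atoms
        for noe in self.noes:
            for a in (*noe.group_i, *noe.group_j):
                if not 0 <= a < n:
                    raise RestraintError(f"NOE references unknown atom {a}")
                if graph.atoms[a][1] != "H":
                    raise RestraintError(f"NOE atom {a} is not a hydrogen")
        bonded = {(min(i, j), max(i, j)) for i, j, _ in graph.bonds}
        for rdc in self.rdcs:
            for h in rdc.atom_h:
                if (min(rdc.atom_c, h), max(rdc.atom_c, h)) not in bonded:
                    raise RestraintError(
                        f"RDC pair C{rdc.atom_c + 1}-H{h + 1} is not bonded"
                    )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^([A-Z][a-z]?)(\d+)$")


def _resolve_label(label: str, graph: MoleculeGraph) -> int:
    m = _LABEL_RE.match(label)
    if not m:
        raise RestraintError(f"cannot parse atom label {label!r}")
    sym, idx1 = m.group(1), int(m.group(2))
    idx = idx1 - 1
    if not 0 <= idx < graph.n_atoms:
        raise RestraintError(f"atom label {label!r}: index out of range")
    if graph.atoms[idx][1] != sym:
        raise RestraintError(
            f"atom label {label!r}: atom {idx1} is {graph.atoms[idx][1]}, not {sym}"
        )
    return idx


def _resolve_group(token: str, graph: MoleculeGraph) -> tuple[int, ...]:
    if token.startswith("@"):
        center = _resolve_label(token[1:], graph)
        hs = graph.hydrogens_on(center)
        if not hs:
            raise RestraintError(f"group {token!r}: atom has no bonded hydrogens")
        return tuple(hs)
    return tuple(_resolve_label(t, graph) for t in token.split("/"))


def atom_label(graph: MoleculeGraph, idx: int) -> str:
    return f"{graph.atoms[idx][1]}{idx + 1}"


def parse_noe_table(
    path: str, graph: MoleculeGraph, half_width: float = 0.10
) -> list[NoeRestraint]:
    """Parse an NOE/ROE table; single-distance rows become r_mean*(1 -/+ half_width)."""
    out = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#")[0].strip().replace(",", " ")
        if not line:
            continue
        toks = line.split()
        if len(toks) not in (3, 4):
            raise RestraintError(f"{path}:{lineno}: expected 3 or 4 columns")
        gi = _resolve_group(toks[0], graph)
        gj = _resolve_group(toks[1], graph)
        vals = [float(t) for t in toks[2:]]
        if any(v <= 0 for v in vals):
            raise RestraintError(f"{path}:{lineno}: non-positive distance")
        if len(vals) == 1:
            r_lo = vals[0] * (1.0 - half_width)
            r_up = vals[0] * (1.0 + half_width)
        else:
            r_lo, r_up = vals
        averaging = "r6" if (len(gi) > 1 or len(gj) > 1) else "none"
        out.append(
            NoeRestraint(gi, gj, r_lo, r_up, averaging=averaging,
                         label=f"{toks[0]}-{toks[1]}")
        )
    return out


def _parse_rdc_line(toks: list[str]) -> tuple[list[str], dict[str, float]]:
    labels, kv = [], {}
    for t in toks:
        if "=" in t:
            k, v = t.split("=")
            kv[k.upper().replace("_", "")] = float(v)
        else:
            try:
                kv.setdefault("D", float(t))
            except ValueError:
                labels.append(t)
    return labels, kv


def parse_rdc_tables(
    paths: list[str], graph: MoleculeGraph
) -> list[RdcRestraint]:
    """Parse one RDC table per alignment medium (medium index = file order)."""
    out: list[RdcRestraint] = []
    for medium, path in enumerate(paths):
        seen = set()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#")[0].strip().replace(",", " ")
            if not line:
                continue
            labels, kv = _parse_rdc_line(line.split())
            if len(labels) not in (2, 3):
                raise RestraintError(f"{path}:{lineno}: expected C plus 1 or 2 H labels")
            c = _resolve_label(labels[0], graph)
            hs = tuple(_resolve_label(h, graph) for h in labels[1:])
            if "D" in kv or "DSUM" in kv:
                d = kv.get("D", kv.get("DSUM"))
            elif "T" in kv and "J" in kv:
                d = (kv["T"] - kv["J"]) / 2.0
            else:
                raise RestraintError(
                    f"{path}:{lineno}: need D= (or bare value) or T= and J="
                )
            key = (c, hs)
            if key in seen:
                raise RestraintError(
                    f"{path}:{lineno}: duplicate RDC entry for {labels}"
                )
            seen.add(key)
            mode = "methylene_sum" if len(hs) == 2 else "single"
            out.append(RdcRestraint(medium, c, hs, float(d), mode=mode))
    rs = RestraintSet(rdcs=out)
    rs.validate(graph)
    return out


# ---------------------------------------------------------------------------
# Writing (round-trip with the parsers above)
# ---------------------------------------------------------------------------

def write_noe_table(path: str, noes: list[NoeRestraint], graph: MoleculeGraph) -> None:
    lines = ["# group_i  group_j  r_lower  r_upper"]
    for noe in noes:
        gi = "/".join(atom_label(graph, a) for a in noe.group_i)
        gj = "/".join(atom_label(graph, a) for a in noe.group_j)
        lines.append(f"{gi}  {gj}  {noe.r_lower:.6f}  {noe.r_upper:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_rdc_tables(
    paths: list[str], rdcs: list[RdcRestraint], graph: MoleculeGraph
) -> None:
    by_medium: dict[int, list[RdcRestraint]] = {}
    for r in rdcs:
        by_medium.setdefault(r.medium, []).append(r)
    for medium, path in enumerate(paths):
        lines = ["# C  H [H2]  D=value (Hz)"]
        for r in by_medium.get(medium, []):
            hs = "  ".join(atom_label(graph, h) for h in r.atom_h)
            lines.append(f"{atom_label(graph, r.atom_c)}  {hs}  D={r.d_exp:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Back-calculation
# ---------------------------------------------------------------------------

def effective_noe_distance(coords: np.ndarray, restraint: NoeRestraint) -> float:
    """<r^-6>-averaged distance over all group_i x group_j proton pairs.

    Reduces to the plain distance for 1x1 groups.  Distances use however many
    coordinate components are present (3D or 4D).
    """
    gi = np.asarray(restraint.group_i)
    gj = np.asarray(restraint.group_j)
    diff = coords[gi][:, None, :] - coords[gj][None, :, :]
    r = np.sqrt((diff ** 2).sum(-1)).ravel()
    if np.any(r < 1e-8):
        raise RestraintError("coincident atoms in NOE group (singular r^-6 average)")
    return float(np.mean(r ** -6.0) ** (-1.0 / 6.0))
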
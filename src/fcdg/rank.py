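"""Configuration fingerprinting and pseudo-energy-ranked ensemble reports.

A *configuration fingerprint* is the vector of chiral-volume signs at every
floating stereocenter plus every prochiral CH2 center, measured on a
minimized 3D structure with a fixed (canonical, index-sorted) substituent
ordering.  Stereocenter signs define the *configuration class* of a
structure; prochiral signs encode diastereotopic proton assignments and are
tracked separately ("pseudo-configurational" changes), mirroring the
distinction between a wrong diastereomer and a wrong CH2 assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .embed import Conformer
from .molgraph import MoleculeGraph

DEGENERATE_VOLUME = 0.01  # A^3; |V| below this is not a trustworthy sign


@dataclass(frozen=True)
class ConfigFingerprint:
    stereo_centers: tuple[int, ...]
    stereo_signs: tuple[int, ...]      # +1 / -1 / 0 (0 = degenerate)
    prochiral_centers: tuple[int, ...]
    prochiral_signs: tuple[int, ...]

    @property
    def degenerate(self) -> bool:
        return 0 in self.stereo_signs

    @property
    def class_key(self) -> tuple[int, ...]:
        return self.stereo_signs

    def mirror(self) -> "ConfigFingerprint":
        return ConfigFingerprint(
            self.stereo_centers, tuple(-s for s in self.stereo_signs),
            self.prochiral_centers, tuple(-s for s in self.prochiral_signs),
        )

    def __str__(self) -> str:
        sym = {1: "+", -1: "-", 0: "?"}
        s = "".join(sym[x] for x in self.stereo_signs)
        p = "".join(sym[x] for x in self.prochiral_signs)
        return f"{s}|{p}" if p else s


def _quad_volume(coords: np.ndarray, quad) -> float:
    p0, p1, p2, p3 = (coords[q] for q in quad)
    return float((p1 - p0) @ np.cross(p2 - p0, p3 - p0))


def floating_centers(
    graph: MoleculeGraph, fixed_centers=()
) -> tuple[list[int], list[int]]:
    stereo = [c for c in graph.stereocenters if c not in set(fixed_centers)]
    return stereo, list(graph.prochiral_centers)


def fingerprint(
    conf: Conformer, graph: MoleculeGraph, fixed_centers=()
) -> ConfigFingerprint:
    """Sign vector of chiral volumes at floating stereo + prochiral centers.

    Substituent ordering is the sorted-neighbor canonical order fixed by the
    constitution, so the fingerprint is stable under rigid motion and flips
    entirely under mirror inversion.  Signs with |V| < 0.01 A^3 are recorded
    as 0 (degenerate).
    """
    if conf.stage != "minimized":
        raise ValueError("fingerprints are defined on minimized 3D structures")
    X = conf.coords[:, :3]
    stereo, prochiral = floating_centers(graph, fixed_centers)

    def sign_at(center):
        quad = graph.neighbors(center)
        v = _quad_volume(X, quad)
        if abs(v) < DEGENERATE_VOLUME:
            return 0
        return 1 if v > 0 else -1

    return ConfigFingerprint(
        stereo_centers=tuple(stereo),
        stereo_signs=tuple(sign_at(c) for c in stereo),
        prochiral_centers=tuple(prochiral),
        prochiral_signs=tuple(sign_at(c) for c in prochiral),
    )


@dataclass
class RankedStructure:
    rank: int               # 1-based, ascending pseudo energy
    seed: int
    e_total: float
    breakdown: dict
    fp: ConfigFingerprint
    degenerate: bool
    failed: bool = False


@dataclass
class EnsembleReport:
    structures: list[RankedStructure]
    class_counts: dict[tuple, int]
    reference: tuple | None
    first_wrong_index: int | None
    first_pseudo_index: int | None
    delta_e_gap: float | None
    n_failed: int = 0
    center_table: list[dict] = field(default_factory=list)

    @property
    def best(self) -> RankedStructure:
        return self.structures[0]

    def to_json(self, path=None) -> str:
        payload = {
            "n_structures": len(self.structures),
            "n_failed": self.n_failed,
            "reference_class": _cls_str(self.reference),
            "first_wrong_index": self.first_wrong_index,
            "first_pseudo_index": self.first_pseudo_index,
            "delta_e_gap": self.delta_e_gap,
            "class_counts": {_cls_str(k): v for k, v in self.class_counts.items()},
            "center_confidence": self.center_table,
            "structures": [
                {"rank": s.rank, "seed": s.seed, "e_total": s.e_total,
                 "fingerprint": str(s.fp), "class": _cls_str(s.fp.class_key),
                 **s.breakdown}
                for s in self.structures
            ],
        }
        text = json.dumps(payload, indent=1)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [
            {"rank": s.rank, "seed": s.seed, "e_total": s.e_total,
             **s.breakdown, "class": _cls_str(s.fp.class_key),
             "fingerprint": str(s.fp), "degenerate": s.degenerate}
            for s in self.structures
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def _cls_str(key) -> str | None:
    if key is None:
        return None
    return "".join({1: "+", -1: "-", 0: "?"}[x] for x in key)


def rank_ensemble(
    confs: list[Conformer],
    graph: MoleculeGraph,
    reference: ConfigFingerprint | tuple | None = None,
    fixed_centers=(),
) -> EnsembleReport:
    """Sort minimized structures by ascending pseudo energy and analyse classes.

    ``reference`` (a fingerprint or a stereo-sign tuple) marks the known/true
    configuration class: the report then contains the 1-based rank of the
    first structure of a different class (``first_wrong_index``), the rank of
    the first structure differing only in prochiral assignment
    (``first_pseudo_index``) and the pseudo-energy gap between the best
    reference-class and best other-class structures.  Without a reference the
    class of the top-ranked structure is used.
    """
    ok = [c for c in confs if not c.failed]
    n_failed = len(confs) - len(ok)
    if not ok:
        raise ValueError("empty ensemble (all structures failed)")
    entries = []
    for c in ok:
        fp = fingerprint(c, graph, fixed_centers)
        entries.append((c.energy.e_total, c.seed, fp, c))
    entries.sort(key=lambda t: (t[0], t[1]))  # stable; tie-break by seed

    structures = [
        RankedStructure(
            rank=i + 1, seed=seed, e_total=e,
            breakdown=c.energy.as_dict(), fp=fp,
            degenerate=fp.degenerate,
        )
        for i, (e, seed, fp, c) in enumerate(entries)
    ]

    usable = [s for s in structures if not s.degenerate]
    if reference is None:
        ref_key = usable[0].fp.class_key if usable else None
    elif isinstance(reference, ConfigFingerprint):
        ref_key = reference.class_key
    else:
        ref_key = tuple(reference)

    class_counts: dict[tuple, int] = {}
    for s in usable:
        class_counts[s.fp.class_key] = class_counts.get(s.fp.class_key, 0) + 1

    first_wrong = None
    first_pseudo = None
    ref_fp = None
    for s in usable:
        if s.fp.class_key == ref_key and ref_fp is None:
            ref_fp = s.fp
        if s.fp.class_key != ref_key and first_wrong is None:
            first_wrong = s.rank
        if (first_pseudo is None and s.fp.class_key == ref_key and ref_fp is not None
                and s.fp.prochiral_signs != ref_fp.prochiral_signs):
            first_pseudo = s.rank

    e_ref = min((s.e_total for s in usable if s.fp.class_key == ref_key), default=None)
    e_wrong = min((s.e_total for s in usable if s.fp.class_key != ref_key), default=None)
    gap = None
    if e_ref is not None and e_wrong is not None:
        gap = e_wrong - e_ref

    report = EnsembleReport(
        structures=structures,
        class_counts=class_counts,
        reference=ref_key,
        first_wrong_index=first_wrong,
        first_pseudo_index=first_pseudo,
        delta_e_gap=gap,
        n_failed=n_failed,
    )
    if len(usable) >= 10:
        report.center_table = center_confidence(report)
    return report


def center_confidence(
    report: EnsembleReport,
    green: float = 1.0,
    amber: float = 0.3,
    decile: float = 0.1,
) -> list[dict]:
    """Per-center assignment confidence ("traffic-light" table).

    For every floating center: the majority sign within the lowest-energy
    decile, the fraction of that decile sharing it, and the pseudo-energy
    difference between the overall best structure and the best structure of
    opposite sign at that center.  Bands: gap >= ``green`` -> green,
    >= ``amber`` -> amber, below -> red (one observed sign only -> green).
    """
    usable = [s for s in report.structures if not s.degenerate]
    if len(usable) < 10:
        raise ValueError("center confidence requires >= 10 usable structures")
    n_dec = max(1, int(round(decile * len(usable))))
    decile_s = usable[:n_dec]
    fp0 = usable[0].fp
    centers = list(fp0.stereo_centers) + list(fp0.prochiral_centers)
    kinds = ["stereo"] * len(fp0.stereo_centers) + ["prochiral"] * len(fp0.prochiral_centers)
    table = []
    for pos, (center, kind) in enumerate(zip(centers, kinds)):
        def sign_of(s):
            fp = s.fp
            if kind == "stereo":
                return fp.stereo_signs[pos]
            return fp.prochiral_signs[pos - len(fp0.stereo_centers)]

        dec_signs = [sign_of(s) for s in decile_s]
        maj = 1 if sum(x > 0 for x in dec_signs) >= sum(x < 0 for x in dec_signs) else -1
        frac = np.mean([x == maj for x in dec_signs])
        e_best = usable[0].e_total
        e_opp = min((s.e_total for s in usable if sign_of(s) == -maj), default=None)
        if e_opp is None:
            gap, band = float("inf"), "green"
        else:
            gap = e_opp - e_best
            band = "green" if gap >= green else ("amber" if gap >= amber else "red")
        table.append({
            "center": int(center), "kind": kind, "majority_sign": int(maj),
            "decile_fraction": float(frac),
            "delta_e_opposite": None if np.isinf(gap) else float(gap),
            "band": band,
        })
    return table
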
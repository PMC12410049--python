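"""Assemble, validate and emit complete multi-species subunit designs.

A design couples three layers: the target geometry (which bond classes
exist and at what angle), the angle modules realizing those angles as
poly-T lengths, and the bond modules realizing specificity as orthogonal
sticky ends.  Each triangular subunit species has three faces (S1-S3);
each active face carries four top and four bottom strands.

Row sequence layout.  Within a row the four strands carry four different
sequences, which prevents faces from binding with a lateral offset, and
the left-to-right order gives each subunit a chirality that prevents
flipping (defining inside/outside surfaces).  Facing rows meet
antiparallel (position 1 against position 4).  A *self-complementary*
bond class (labels sA, sB) therefore uses the palindromic row motif
[a, b, b*, a*], which binds an identical row on the partner face; a
*heterotypic* class (A binding A*) puts four independent sequences on
the face carrying the unstarred label and their position-reversed
complements on the starred face.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .anglemod import AngleModule, sticky_length_for
from .geometry import StructureKind, TargetStructure
from .sequences import (
    DEFAULT_SALT,
    OrthogonalSet,
    SaltModel,
    StickyEnd,
    generate_orthogonal_set,
    reverse_complement,
    verify_orthogonal_set,
)

__all__ = [
    "BondClass",
    "FaceSpec",
    "SubunitSpec",
    "AssemblyConditions",
    "DesignBundle",
    "ValidationReport",
    "EconomyMetrics",
    "OligoRecord",
    "build_design",
    "validate_design",
    "economy_metrics",
    "emit_oligos",
    "placeholder_anchor_map",
    "interaction_matrix_signature",
]

FACE_IDS = ("S1", "S2", "S3")
ROWS = ("top", "bottom")
STRANDS_PER_ROW = 4
TOTAL_STAPLES = 204  # core staples per subunit; 24 of them are extended
SCHEMA_VERSION = 1


@dataclass(frozen=True)
class BondClass:
    """One bond of the interaction matrix and its sticky-end realization."""

    label: str
    partner_label: str
    top_bp: int
    bottom_bp: int
    hierarchical: bool = False

    @property
    def self_complementary(self) -> bool:
        return self.label == self.partner_label


@dataclass
class FaceSpec:
    """One face of a subunit: angle module, bond label and row sequences."""

    face_id: str
    angle_module: AngleModule
    bond_label: Optional[str]
    top_sticky: list[str] = field(default_factory=list)
    bottom_sticky: list[str] = field(default_factory=list)

    @property
    def active(self) -> bool:
        return self.bond_label is not None

    def __post_init__(self) -> None:
        if self.face_id not in FACE_IDS:
            raise ValueError(f"face_id {self.face_id} not in {FACE_IDS}")
        if self.active:
            if len(self.top_sticky) != 4 or len(self.bottom_sticky) != 4:
                raise ValueError("active face needs 4 top + 4 bottom sticky labels")
        elif self.top_sticky or self.bottom_sticky:
            raise ValueError("passivated face carries no sticky ends")


@dataclass
class SubunitSpec:
    """A subunit species: three faces and a stoichiometric ratio."""

    species_id: str
    faces: list[FaceSpec]
    stoichiometry: float = 1.0

    def __post_init__(self) -> None:
        if [f.face_id for f in self.faces] != list(FACE_IDS):
            raise ValueError("subunit needs exactly faces S1, S2, S3 in order")

    @property
    def valency(self) -> int:
        return sum(f.active for f in self.faces)


@dataclass(frozen=True)
class AssemblyConditions:
    """Advisory wet-lab conditions attached to a recipe (not computed)."""

    temperature_C: float
    time_h: float
    mgcl2_mM: float = 20.0
    subunit_concentration_nM: float = 5.0


@dataclass
class DesignBundle:
    """A complete design: species, interaction matrix and sticky-end set."""

    target: TargetStructure
    species: list[SubunitSpec]
    bond_classes: dict[str, BondClass]
    sticky_set: OrthogonalSet
    assembly_conditions: AssemblyConditions
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def sticky_by_label(self) -> dict[str, StickyEnd]:
        return {e.label: e for e in self.sticky_set.ends}

    def subunits_per_structure(self) -> Optional[int]:
        t = self.target
        if t.kind is StructureKind.SHELL:
            return 20 * t.T
        if t.kind is StructureKind.TUBE:
            return 3 * t.m  # three-layer tubelet
        if t.kind is StructureKind.VERTEX:
            return t.n_fold
        return None  # unbounded tilings

    def to_json(self, path=None) -> str:
        doc = {
            "schema_version": self.schema_version,
            "target": {
                "kind": self.target.kind.value,
                **{
                    k: getattr(self.target, k)
                    for k in ("T", "h", "k", "m", "n_fold")
                    if getattr(self.target, k) is not None
                },
            },
            "seed": self.seed,
            "assembly_conditions": vars(self.assembly_conditions).copy(),
            "bond_classes": {
                lab: {
                    "partner": bc.partner_label,
                    "top_bp": bc.top_bp,
                    "bottom_bp": bc.bottom_bp,
                    "hierarchical": bc.hierarchical,
                }
                for lab, bc in sorted(self.bond_classes.items())
            },
            "species": [
                {
                    "species_id": sp.species_id,
                    "stoichiometry": sp.stoichiometry,
                    "faces": [
                        {
                            "face_id": f.face_id,
                            "active": f.active,
                            "bond": f.bond_label,
                            "l_top": None if not f.active else f.angle_module.l_top,
                            "l_bottom": None
                            if not f.active
                            else f.angle_module.l_bottom,
                            "top_sticky": f.top_sticky,
                            "bottom_sticky": f.bottom_sticky,
                        }
                        for f in sp.faces
                    ],
                }
                for sp in self.species
            ],
            "sticky_ends": [
                {"label": e.label, "sequence": e.sequence, "partner": e.partner_label}
                for e in self.sticky_set.ends
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# recipe construction


def _row_labels(bond: BondClass, row: str, starred_side: bool) -> list[str]:
    """Sticky labels of one row of a face carrying ``bond``.

    Self-complementary classes use the palindromic motif [a, b, b*, a*].
    Heterotypic classes: the unstarred face carries [x1..x4]; the starred
    face carries the position-reversed complements [x4*, x3*, x2*, x1*].
    """
    base = bond.label.rstrip("*")
    r = row[0]  # 't' / 'b'
    if bond.self_complementary:
        return [f"{base}.{r}1", f"{base}.{r}2", f"{base}.{r}2*", f"{base}.{r}1*"]
    if not starred_side:
        return [f"{base}.{r}{i}" for i in (1, 2, 3, 4)]
    return [f"{base}.{r}{i}*" for i in (4, 3, 2, 1)]


def _elementary_demand(bonds: dict[str, BondClass]) -> tuple[list[str], list[int]]:
    """Elementary sticky-pair labels and lengths needed by a set of bonds."""
    labels: list[str] = []
    lengths: list[int] = []
    seen = set()
    for bond in bonds.values():
        base = bond.label.rstrip("*")
        if base in seen:
            continue
        seen.add(base)
        n = 2 if bond.self_complementary else 4
        for i in range(1, n + 1):
            labels.append(f"{base}.t{i}")
            lengths.append(bond.top_bp)
        for i in range(1, n + 1):
            labels.append(f"{base}.b{i}")
            lengths.append(bond.bottom_bp)
    return labels, lengths


def _face(face_id: str, bond: Optional[BondClass], module: Optional[AngleModule]) -> FaceSpec:
    if bond is None:
        return FaceSpec(face_id, AngleModule(0, 0, passivated=True), None)
    starred = bond.label.endswith("*")
    return FaceSpec(
        face_id,
        module,
        bond.label,
        top_sticky=_row_labels(bond, "top", starred),
        bottom_sticky=_row_labels(bond, "bottom", starred),
    )


def _mk_bonds(specs: list[tuple[str, int, int, bool]]) -> dict[str, BondClass]:
    """Build a bond-class table from (label, top_bp, bottom_bp, hierarchical).

    Labels starting with 's' are self-complementary; any other label L also
    registers its partner L*.
    """
    out: dict[str, BondClass] = {}
    for label, top_bp, bottom_bp, hier in specs:
        if label.startswith("s"):
            out[label] = BondClass(label, label, top_bp, bottom_bp, hier)
        else:
            out[label] = BondClass(label, label + "*", top_bp, bottom_bp, hier)
            out[label + "*"] = BondClass(label + "*", label, top_bp, bottom_bp, hier)
    return out


FLAT = AngleModule(3, 3)
CONVEX = AngleModule(14, 3)  # 41.8 degree structural angle
CONCAVE = AngleModule(3, 8)  # negative (tube axial) angle


def build_design(
    target: TargetStructure,
    seed: int = 0,
    single_angle_module: bool = False,
    salt: SaltModel = DEFAULT_SALT,
    dG_window: float = 1.0,
    max_crosstalk: int = 3,
) -> DesignBundle:
    """Build the demonstrated design for ``target``.

    Recipes: continuous tiling (1 species, one self-complementary bond on
    all faces, flat modules); tetramer tiling (yellow:green 3:1, bonds
    A/A*/B vs B*, flat); T=1 shell (1 species, self-complementary bond,
    convex modules, 6/5 bp); T=4 shell (3:1, A/A* convex at 6/5 bp,
    hierarchical 7 bp B/B* flat); (m,0) tube (yellow:green:purple 1:1:1,
    purple S3 passivated); 5-fold vertex (1 species, S3 passivated) and
    6-fold vertex (2 species forced to alternate).  With
    ``single_angle_module`` the T=4 shell uses the flexible convex module
    on every face (one angle module serving both 0° and 41.8° bonds).
    """
    kind = target.kind
    if kind is StructureKind.CONTINUOUS_TILING:
        bonds = _mk_bonds([("sA", 5, 5, False)])
        species = [
            SubunitSpec(
                "yellow",
                [_face(fid, bonds["sA"], FLAT) for fid in FACE_IDS],
                stoichiometry=1.0,
            )
        ]
        conditions = AssemblyConditions(28.0, 36.0)
    elif kind is StructureKind.TETRAMER_TILING:
        bonds = _mk_bonds([("A", 5, 5, False), ("B", 5, 5, False)])
        species = [
            SubunitSpec(
                "yellow",
                [
                    _face("S1", bonds["A"], FLAT),
                    _face("S2", bonds["A*"], FLAT),
                    _face("S3", bonds["B"], FLAT),
                ],
                stoichiometry=3.0,
            ),
            SubunitSpec(
                "green",
                [_face(fid, bonds["B*"], FLAT) for fid in FACE_IDS],
                stoichiometry=1.0,
            ),
        ]
        conditions = AssemblyConditions(28.0, 36.0)
    elif kind is StructureKind.SHELL and target.T == 1:
        bonds = _mk_bonds([("sA", 6, 5, False)])
        species = [
            SubunitSpec(
                "yellow",
                [_face(fid, bonds["sA"], CONVEX) for fid in FACE_IDS],
                stoichiometry=1.0,
            )
        ]
        conditions = AssemblyConditions(25.0, 24.0)
    elif kind is StructureKind.SHELL and target.T == 4:
        bonds = _mk_bonds([("A", 6, 5, False), ("B", 7, 7, True)])
        flat = CONVEX if single_angle_module else FLAT
        species = [
            SubunitSpec(
                "yellow",
                [
                    _face("S1", bonds["A"], CONVEX),
                    _face("S2", bonds["A*"], CONVEX),
                    _face("S3", bonds["B"], flat),
                ],
                stoichiometry=3.0,
            ),
            SubunitSpec(
                "green",
                [_face(fid, bonds["B*"], flat) for fid in FACE_IDS],
                stoichiometry=1.0,
            ),
        ]
        conditions = AssemblyConditions(30.0, 96.0)
    elif kind is StructureKind.SHELL:
        raise ValueError(
            f"T={target.T} shell not demonstrated in source; supported: T in {{1, 4}}"
        )
    elif kind is StructureKind.TUBE:
        bonds = _mk_bonds(
            [
                ("sA", 6, 5, False),
                ("sB", 6, 5, False),
                ("A", 5, 5, False),
                ("B", 6, 5, False),
                ("C", 6, 5, False),
            ]
        )
        species = [
            SubunitSpec(
                "yellow",
                [
                    _face("S1", bonds["sA"], CONVEX),
                    _face("S2", bonds["sB"], CONVEX),
                    _face("S3", bonds["A"], CONCAVE),
                ],
                stoichiometry=1.0,
            ),
            SubunitSpec(
                "green",
                [
                    _face("S1", bonds["B"], CONVEX),
                    _face("S2", bonds["C"], CONVEX),
                    _face("S3", bonds["A*"], CONCAVE),
                ],
                stoichiometry=1.0,
            ),
            SubunitSpec(
                "purple",
                [
                    _face("S1", bonds["B*"], CONVEX),
                    _face("S2", bonds["C*"], CONVEX),
                    _face("S3", None, None),
                ],
                stoichiometry=1.0,
            ),
        ]
        conditions = AssemblyConditions(30.0, 96.0)
    elif kind is StructureKind.VERTEX and target.n_fold == 5:
        bonds = _mk_bonds([("sA", 6, 5, False)])
        species = [
            SubunitSpec(
                "yellow",
                [
                    _face("S1", bonds["sA"], CONVEX),
                    _face("S2", bonds["sA"], CONVEX),
                    _face("S3", None, None),
                ],
                stoichiometry=1.0,
            )
        ]
        conditions = AssemblyConditions(25.0, 24.0)
    elif kind is StructureKind.VERTEX and target.n_fold == 6:
        # two species forced to alternate: only even rings can close
        bonds = _mk_bonds([("A", 6, 5, False), ("B", 6, 5, False)])
        species = [
            SubunitSpec(
                "yellow",
                [
                    _face("S1", bonds["A"], CONVEX),
                    _face("S2", bonds["B"], CONVEX),
                    _face("S3", None, None),
                ],
                stoichiometry=1.0,
            ),
            SubunitSpec(
                "green",
                [
                    _face("S1", bonds["A*"], CONVEX),
                    _face("S2", bonds["B*"], CONVEX),
                    _face("S3", None, None),
                ],
                stoichiometry=1.0,
            ),
        ]
        conditions = AssemblyConditions(25.0, 24.0)
    else:
        raise ValueError(
            f"unsupported target {kind.value} (n_fold={target.n_fold}); supported: "
            "continuous_tiling, tetramer_tiling, shell T=1/T=4, tube m>=4, "
            "vertex n_fold in {5, 6}"
        )

    labels, lengths = _elementary_demand(bonds)
    sticky = generate_orthogonal_set(
        len(labels),
        lengths,
        dG_window=dG_window,
        max_crosstalk=max_crosstalk,
        seed=seed,
        salt=salt,
        labels=labels,
    )
    return DesignBundle(
        target=target,
        species=species,
        bond_classes=bonds,
        sticky_set=sticky,
        assembly_conditions=conditions,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _row_sequences(face: FaceSpec, row: str, sticky: dict[str, StickyEnd]) -> list[str]:
    labels = face.top_sticky if row == "top" else face.bottom_sticky
    return [sticky[lab].sequence for lab in labels if lab in sticky]


def validate_design(
    bundle: DesignBundle,
    max_crosstalk: int = 3,
    dG_window: float = 1.0,
) -> ValidationReport:
    """Check a bundle against the structural and sequence design rules.

    Reports (never raises): anti-offset (four distinct sequences per row),
    chirality (self-complementary rows match the palindromic [a,b,b*,a*]
    motif, heterotypic partner rows are position-reversed complements, top
    and bottom rows differ), complementarity closure (every active bond has
    its partner on some face), sticky-set orthogonality and ΔG window
    (delegated to the exhaustive verifier), angle-module compatibility of
    paired faces, and that passivated faces leave no partner dangling.
    """
    rep = ValidationReport()
    sticky = bundle.sticky_by_label()
    carried: dict[str, list[tuple[str, FaceSpec]]] = {}
    for sp in bundle.species:
        for face in sp.faces:
            if not face.active:
                continue
            carried.setdefault(face.bond_label, []).append((sp.species_id, face))
            where = f"{sp.species_id}/{face.face_id}"
            for row, labels in (("top", face.top_sticky), ("bottom", face.bottom_sticky)):
                missing = [lab for lab in labels if lab not in sticky]
                if missing:
                    rep.violations.append(f"{where} {row}: unknown sticky {missing}")
                    continue
                seqs = [sticky[lab].sequence for lab in labels]
                if len(set(labels)) != 4 or len(set(seqs)) != 4:
                    rep.violations.append(
                        f"anti-offset: {where} {row} row repeats a sequence"
                    )
            top = _row_sequences(face, "top", sticky)
            bottom = _row_sequences(face, "bottom", sticky)
            if top and bottom and set(top) == set(bottom):
                rep.violations.append(
                    f"chirality: {where} top and bottom rows identical"
                )
            bond = bundle.bond_classes.get(face.bond_label)
            if bond is None:
                rep.violations.append(f"{where}: unknown bond class {face.bond_label}")
                continue
            if bond.self_complementary:
                for row, seqs in (("top", top), ("bottom", bottom)):
                    if len(seqs) == 4 and not (
                        seqs[3] == reverse_complement(seqs[0])
                        and seqs[2] == reverse_complement(seqs[1])
                    ):
                        rep.violations.append(
                            f"chirality: {where} {row} row of self-complementary "
                            f"{bond.label} does not match the [a,b,b*,a*] motif"
                        )

    # closure + paired-face compatibility
    for label, faces in carried.items():
        bond = bundle.bond_classes.get(label)
        if bond is None:
            continue
        partner_faces = carried.get(bond.partner_label, [])
        if not partner_faces:
            rep.violations.append(
                f"closure: bond {label} has no face carrying partner "
                f"{bond.partner_label}"
            )
            continue
        for _, fa in faces:
            for _, fb in partner_faces:
                if (fa.angle_module.l_top, fa.angle_module.l_bottom) != (
                    fb.angle_module.l_top,
                    fb.angle_module.l_bottom,
                ):
                    rep.violations.append(
                        f"angle modules of paired faces differ on bond {label}: "
                        f"({fa.angle_module.l_top},{fa.angle_module.l_bottom}) vs "
                        f"({fb.angle_module.l_top},{fb.angle_module.l_bottom})"
                    )
                ta = _row_sequences(fa, "top", sticky)
                tb = _row_sequences(fb, "top", sticky)
                if len(ta) == 4 and len(tb) == 4 and not bond.self_complementary:
                    expect = [reverse_complement(s) for s in reversed(ta)]
                    if tb != expect:
                        rep.violations.append(
                            f"chirality: top rows of bond {label} faces are not "
                            "position-reversed complements"
                        )

    seq_report = verify_orthogonal_set(
        bundle.sticky_set.ends,
        max_crosstalk=max_crosstalk,
        dG_window=dG_window,
        temperature=bundle.sticky_set.temperature,
        salt=bundle.sticky_set.salt,
    )
    rep.violations.extend(f"sequence set: {v}" for v in seq_report.violations)
    return rep


# ---------------------------------------------------------------------------
# economy metrics & oligo emission


@dataclass
class EconomyMetrics:
    """Per-species oligo economy of the modular design."""

    per_species: dict[str, dict[str, float]]
    total_staples: int = TOTAL_STAPLES

    @property
    def max_variable_strands(self) -> int:
        return max(int(v["variable_strands"]) for v in self.per_species.values())

    @property
    def max_modified_fraction_pct(self) -> float:
        return max(v["modified_fraction_pct"] for v in self.per_species.values())


def economy_metrics(bundle: DesignBundle) -> EconomyMetrics:
    """Variable strand counts: 8 per active face of the 204 core staples."""
    per = {}
    for sp in bundle.species:
        variable = 8 * sp.valency
        per[sp.species_id] = {
            "active_faces": sp.valency,
            "variable_strands": variable,
            "total_staples": TOTAL_STAPLES,
            "modified_fraction_pct": 100.0 * variable / TOTAL_STAPLES,
        }
    return EconomyMetrics(per_species=per)


@dataclass(frozen=True)
class OligoRecord:
    oligo_id: str
    species: str
    face: str
    row: str
    position: int
    sequence: str


def placeholder_anchor_map(anchor_length: int = 16, seed: int = 42) -> dict[str, str]:
    """Synthetic placeholder anchors for the 24 extension positions.

    These are deterministic random sequences standing in for the core
    staple anchor segments, which are design-specific; they are clearly
    non-functional and must be replaced with real anchors (loaded from
    CSV) before ordering oligos.
    """
    rng = random.Random(seed)
    out = {}
    for fid in FACE_IDS:
        for row in ROWS:
            for pos in range(1, STRANDS_PER_ROW + 1):
                out[f"{fid}.{row}.{pos}"] = "".join(
                    rng.choice("ACGT") for _ in range(anchor_length)
                )
    return out


def emit_oligos(
    bundle: DesignBundle,
    anchor_map: Optional[dict[str, str]] = None,
) -> list[OligoRecord]:
    """Emit one record per variable strand: anchor ⧺ poly-T ⧺ sticky, 5'→3'.

    ``anchor_map`` maps "S1.top.1"-style position keys to anchor sequences;
    the default is the synthetic placeholder map.  Passivated faces emit
    nothing.  Ordering is deterministic (species, face, row, position).
    """
    if anchor_map is None:
        anchor_map = placeholder_anchor_map()
    sticky = bundle.sticky_by_label()
    records: list[OligoRecord] = []
    for sp in bundle.species:
        for face in sp.faces:
            if not face.active:
                continue
            module = face.angle_module
            for row, labels, l_polyt in (
                ("top", face.top_sticky, module.l_top),
                ("bottom", face.bottom_sticky, module.l_bottom),
            ):
                for pos, lab in enumerate(labels, start=1):
                    key = f"{face.face_id}.{row}.{pos}"
                    if key not in anchor_map:
                        raise ValueError(f"missing anchor for active position {key}")
                    seq = anchor_map[key] + "T" * l_polyt + sticky[lab].sequence
                    records.append(
                        OligoRecord(
                            oligo_id=f"{sp.species_id}/{face.face_id}/{row}/{pos}",
                            species=sp.species_id,
                            face=face.face_id,
                            row=row,
                            position=pos,
                            sequence=seq,
                        )
                    )
    return records


def oligos_to_dataframe(records: list[OligoRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.oligo_id,
                "species": r.species,
                "face": r.face,
                "row": r.row,
                "position": r.position,
                "sequence": r.sequence,
            }
            for r in records
        ]
    )


def oligos_to_fasta(records: list[OligoRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.oligo_id}\n{r.sequence}\n")


def interaction_matrix_signature(bundle: DesignBundle) -> dict[tuple[str, str], Optional[str]]:
    """The (species, face) → bond-label map, for comparing matrices."""
    return {
        (sp.species_id, f.face_id): f.bond_label
        for sp in bundle.species
        for f in sp.faces
    }
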
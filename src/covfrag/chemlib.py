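"""Covalent-fragment library triage.

Descriptor computation, heavy-atom/logP window filtering, warhead-class
substructure classification and rule-of-three profiling for electrophilic
fragment libraries.

The library model assumes five warhead (covalent reactive group) families:

* ``AA`` — acrylamides (Michael acceptors, generally mild),
* ``CA`` — alpha-cyanoacrylamides/acrylates (potentially reversible
  thia-Michael addition),
* ``EO`` — epoxides (strained three-membered ethers, two electrophilic
  carbons),
* ``VS`` — vinyl sulfones (activated Michael acceptors),
* ``SN`` — electron-deficient N-heteroarenes carrying a leaving group
  (halogen or alkylsulfonyl) on a ring carbon, reactive via nucleophilic
  aromatic substitution (SNAr).

Classification precedence is CA, VS, AA, EO, SN: the alpha-cyano and
sulfone patterns are supersets of the plain acrylamide motif and must be
checked first; SNAr is checked last because heteroaryl halides may coexist
with a Michael acceptor that dominates reactivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

__all__ = [
    "Structure",
    "DescriptorSet",
    "WarheadClass",
    "FilterDecision",
    "StructureParseError",
    "compute_descriptors",
    "apply_size_logp_filter",
    "classify_warhead",
    "rule_of_three_profile",
    "WARHEAD_SMARTS",
]


class StructureParseError(ValueError):
    """Raised when a line notation cannot be parsed into a molecule."""


@dataclass(frozen=True)
class Structure:
    """A library member: an identifier plus its SMILES line notation."""

    id: str
    line_notation: str
    source: str = ""

    def to_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.line_notation)
        if mol is None:
            raise StructureParseError(
                f"structure {self.id!r}: cannot parse SMILES {self.line_notation!r}"
            )
        return mol


@dataclass(frozen=True)
class DescriptorSet:
    """Physicochemical profile used for fragment-library triage.

    ``logp`` is the Wildman–Crippen atom-contribution octanol/water
    partition coefficient; ``psa`` is the topological polar surface area
    in Å²; ``rotatable_bonds`` uses the strict definition (non-ring single
    bonds between non-terminal heavy atoms, amide C–N excluded).
    """

    heavy_atoms: int
    mol_weight: float
    logp: float
    hbd: int
    hba: int
    rotatable_bonds: int
    psa: float


@dataclass(frozen=True)
class WarheadClass:
    family: str  # one of AA, CA, EO, VS, SN, none
    sn_ring: str = "n/a"  # five-membered / six-membered / bicyclic, SN only

    def __post_init__(self) -> None:
        if (self.family == "SN") != (self.sn_ring != "n/a"):
            raise ValueError("sn_ring must be set iff family is SN")


@dataclass(frozen=True)
class FilterDecision:
    id: str
    pass_size: bool
    pass_logp: bool
    rule_of_three_violations: frozenset[str] = field(default_factory=frozenset)

    @property
    def pass_overall(self) -> bool:
        return self.pass_size and self.pass_logp


def compute_descriptors(structure: Structure) -> DescriptorSet:
    """Compute the seven triage descriptors for one structure.

    Raises :class:`StructureParseError` (naming the offending id) when the
    line notation does not parse.
    """
    mol = structure.to_mol()
    return DescriptorSet(
        heavy_atoms=mol.GetNumHeavyAtoms(),
        mol_weight=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(
            mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
        ),
        psa=rdMolDescriptors.CalcTPSA(mol),
    )


def apply_size_logp_filter(
    d: DescriptorSet,
    id: str = "",
    min_ha: int = 6,
    max_ha: int = 22,
    max_logp: float = 2.0,
) -> FilterDecision:
    """Size/lipophilicity window filter for library assembly.

    Keeps fragments with ``min_ha <= heavy_atoms <= max_ha`` and
    ``logp <= max_logp``; all boundaries are inclusive (a 22-heavy-atom
    fragment with logP exactly 2.0 passes).
    """
    return FilterDecision(
        id=id,
        pass_size=min_ha <= d.heavy_atoms <= max_ha,
        pass_logp=d.logp <= max_logp,
        rule_of_three_violations=rule_of_three_profile(d),
    )


def rule_of_three_profile(d: DescriptorSet) -> frozenset[str]:
    """Return the set of rule-of-three guideline violations.

    Thresholds: MW ≤ 300 g/mol, HBD ≤ 3, HBA ≤ 3, rotatable bonds ≤ 3,
    PSA ≤ 60 Å²; a descriptor strictly above its threshold is a violation.
    """
    violations = set()
    if d.mol_weight > 300:
        violations.add("MW")
    if d.hbd > 3:
        violations.add("HBD")
    if d.hba > 3:
        violations.add("HBA")
    if d.rotatable_bonds > 3:
        violations.add("ROTB")
    if d.psa > 60:
        violations.add("PSA")
    return frozenset(violations)


# Versioned warhead SMARTS set (v1). Order is the classification
# precedence; the first matching family wins.
WARHEAD_SMARTS: tuple[tuple[str, str], ...] = (
    # alpha-cyanoacrylamide / alpha-cyanoacrylate
    ("CA", "[CX3]=[CX3]([CX2]#[NX1])[CX3](=O)[#7,#8]"),
    # vinyl sulfone
    ("VS", "[CX3]=[CX3][SX4](=[OX1])(=[OX1])"),
    # acrylamide (N-substituted or not)
    ("AA", "[CX3]=[CX3][CX3](=O)[NX3]"),
    # epoxide
    ("EO", "[C;r3]1[O;r3][C;r3]1"),
    # SNAr: aromatic carbon bearing halogen or alkyl/aryl-sulfonyl;
    # ring-context (aromatic N in the same ring) is checked in code.
    ("SN", "[c]-[F,Cl,Br,I,$([SX4](=[OX1])(=[OX1])[#6])]"),
)

_COMPILED = tuple((fam, Chem.MolFromSmarts(s)) for fam, s in WARHEAD_SMARTS)


def _sn_ring_subtype(mol: Chem.Mol, carbon_idx: int) -> str | None:
    """Ring subtype of the SNAr-reactive carbon, or None if the carbon is
    not part of an aromatic N-heterocycle."""
    ring_info = mol.GetRingInfo()
    rings = [
        r
        for r in ring_info.AtomRings()
        if carbon_idx in r
        and all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r)
        and any(mol.GetAtomWithIdx(i).GetAtomicNum() == 7 for i in r)
    ]
    if not rings:
        return None
    ring = min(rings, key=len)
    # fused aromatic system -> bicyclic
    for other in ring_info.AtomRings():
        if tuple(other) == tuple(ring):
            continue
        shared = set(other) & set(ring)
        if len(shared) >= 2 and all(
            mol.GetAtomWithIdx(i).GetIsAromatic() for i in other
        ):
            return "bicyclic"
    return "five-membered" if len(ring) == 5 else "six-membered"


def classify_warhead(structure: Structure) -> WarheadClass:
    """Assign exactly one warhead family (deterministic precedence).

    Molecules matching no pattern are labelled ``none``. SNAr hits are
    additionally subtyped by the ring system carrying the leaving group
    (five-membered, six-membered, or bicyclic fused aromatic).
    """
    mol = structure.to_mol()
    for family, patt in _COMPILED:
        matches = mol.GetSubstructMatches(patt)
        if not matches:
            continue
        if family != "SN":
            return WarheadClass(family=family)
        for match in matches:
            subtype = _sn_ring_subtype(mol, match[0])
            if subtype is not None:
                return WarheadClass(family="SN", sn_ring=subtype)
    return WarheadClass(family="none")
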
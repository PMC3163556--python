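"""Structure handling: parsing, fragment fingerprints, Tanimoto similarity,
and rule-based metabolite generation.

Molecules are parsed from SMILES and carry a canonical form so that any two
atom-order permutations of the same structure compare equal.  Fingerprints are
hashed linear-fragment (path) fingerprints: every bond path of length 1..L is
enumerated and hashed into a fixed-length bit vector, the classic framework for
Tanimoto similarity searching.  The fingerprint descriptor string is recorded
on every fingerprint so downstream similarity values are reproducible.

Metabolite generation applies user-replaceable empirical biotransformation
rules written as reaction SMARTS (ester hydrolysis, aromatic hydroxylation,
O-demethylation, amide hydrolysis are shipped as defaults).  Predicted
metabolites join their parent as similarity-search queries.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from .errors import FormatError, RuleApplicationError, StructureParseError

RDLogger.DisableLog("rdApp.*")

DEFAULT_PATH_LENGTH = 7  # max fragment path length, bonds
DEFAULT_N_BITS = 1024


@dataclass(frozen=True)
class Molecule:
    """A parsed structure.

    ``canonical_form`` is the RDKit canonical isomeric SMILES; identical for
    any atom-order permutation of the same structure.  ``role`` is ``parent``
    for input compounds and ``metabolite`` for rule products, in which case
    ``parent_id`` and ``rule`` record the provenance.
    """

    id: str
    smiles: str
    canonical_form: str
    heavy_atom_count: int
    role: str = "parent"
    parent_id: str | None = None
    rule: str | None = None
    _mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def mol(self) -> Chem.Mol:
        if self._mol is not None:
            return self._mol
        return Chem.MolFromSmiles(self.canonical_form)


@dataclass(frozen=True)
class FingerprintScheme:
    """Parameters of the hashed linear-fragment fingerprint."""

    max_path: int = DEFAULT_PATH_LENGTH
    n_bits: int = DEFAULT_N_BITS

    @property
    def descriptor(self) -> str:
        return f"linear-path;L={self.max_path};B={self.n_bits}"


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length fragment bit signature, stored as the set of on bits."""

    bits: frozenset[int]
    length: int
    descriptor: str

    def __post_init__(self):
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.length):
            raise ValueError("fingerprint bit position out of range")


@dataclass(frozen=True)
class MetabolicRule:
    """One empirical biotransformation rule.

    ``reactant_pattern`` (SMARTS) pre-screens substrates; ``transformation``
    is a reaction SMARTS whose products are the predicted metabolites.
    ``max_applications`` bounds how many successive applications of the rule
    are attempted on one substrate (1 = single-site products only).
    """

    name: str
    reactant_pattern: str
    transformation: str
    phase: str = "I"
    max_applications: int = 1

    def __post_init__(self):
        if Chem.MolFromSmarts(self.reactant_pattern) is None:
            raise FormatError(
                f"rule {self.name!r}: reactant_pattern does not parse as SMARTS"
            )
        if self.max_applications < 1:
            raise FormatError(f"rule {self.name!r}: max_applications must be >= 1")

    @property
    def query(self) -> Chem.Mol:
        return Chem.MolFromSmarts(self.reactant_pattern)

    @property
    def reaction(self) -> AllChem.ChemicalReaction:
        rxn = AllChem.ReactionFromSmarts(self.transformation)
        if rxn is None:
            raise FormatError(f"rule {self.name!r}: transformation does not parse")
        return rxn


def parse_structure(input_id: str, smiles: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule` with canonical form.

    Raises :class:`StructureParseError` naming the offending input on
    unparsable SMILES.
    """
    if not smiles:
        raise StructureParseError(input_id, smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(input_id, smiles)
    return Molecule(
        id=input_id,
        smiles=smiles,
        canonical_form=Chem.MolToSmiles(mol),
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        _mol=mol,
    )


def compute_fingerprint(
    m: Molecule, scheme: FingerprintScheme = FingerprintScheme()
) -> Fingerprint:
    """Hashed linear-fragment fingerprint of a molecule.

    Bond paths of length 1..L are enumerated and hashed; single atoms
    (length-0 paths) are hashed by element so even a one-atom molecule has a
    nonempty signature.  Deterministic for a given scheme and invariant to
    input atom ordering (fingerprinting operates on the parsed graph, not the
    SMILES text).
    """
    mol = m.mol
    bv = Chem.RDKFingerprint(
        mol,
        minPath=1,
        maxPath=scheme.max_path,
        fpSize=scheme.n_bits,
        branchedPaths=False,
    )
    bits = set(bv.GetOnBits())
    for atom in mol.GetAtoms():
        bits.add((atom.GetAtomicNum() * 0x9E3779B1 + 7) % scheme.n_bits)
    return Fingerprint(
        bits=frozenset(bits),
        length=scheme.n_bits,
        descriptor=scheme.descriptor,
    )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient T = |A∩B| / |A∪B| of two bit sets.

    Symmetric; 1 for identical nonempty sets; by convention 0 when both sets
    are empty (avoids 0/0).  Raises ``ValueError`` on mismatched bit lengths.
    """
    if a.length != b.length:
        raise ValueError(
            f"fingerprint length mismatch: {a.length} vs {b.length}"
        )
    union = a.bits | b.bits
    if not union:
        return 0.0
    return len(a.bits & b.bits) / len(union)


def _sanitized_products(rule: MetabolicRule, mol: Chem.Mol) -> list[Chem.Mol]:
    """Run one rule over one substrate; one product set per matching site."""
    out = []
    for product_tuple in rule.reaction.RunReactants((mol,)):
        for prod in product_tuple:
            try:
                Chem.SanitizeMol(prod)
            except Exception as exc:  # pragma: no cover - rdkit detail
                raise RuleApplicationError(rule.name, str(exc)) from exc
            if prod.GetNumHeavyAtoms() >= 1:
                out.append(prod)
    return out


def generate_metabolites(
    m: Molecule, rules: Sequence[MetabolicRule], depth: int = 1
) -> list[Molecule]:
    """Predict metabolites of a parent molecule by empirical rules.

    Each rule is applied at every matching site (one product per site);
    ``max_applications`` on the rule allows repeated application to its own
    products within one generation step.  ``depth`` > 1 additionally feeds all
    products of one pass through the whole rule set again
    (metabolites-of-metabolites); the default is single-pass metabolism.

    Products are deduplicated by canonical form; products identical to the
    parent are dropped.  Raises :class:`RuleApplicationError` when a rule
    yields an unparsable product.
    """
    if m.role != "parent":
        raise ValueError("generate_metabolites requires a parent molecule")

    seen: dict[str, tuple[str, Chem.Mol]] = {}  # canonical -> (rule name, mol)
    substrates = [m.mol]
    for _ in range(depth):
        next_substrates: list[Chem.Mol] = []
        for sub in substrates:
            for rule in rules:
                if not sub.HasSubstructMatch(rule.query):
                    continue
                layer = [sub]
                for _ in range(rule.max_applications):
                    produced: list[Chem.Mol] = []
                    for s in layer:
                        if not s.HasSubstructMatch(rule.query):
                            continue
                        produced.extend(_sanitized_products(rule, s))
                    for p in produced:
                        can = Chem.MolToSmiles(p)
                        if can != m.canonical_form and can not in seen:
                            seen[can] = (rule.name, p)
                            next_substrates.append(p)
                    layer = produced
        substrates = next_substrates
        if not substrates:
            break

    metabolites = []
    for i, can in enumerate(sorted(seen), start=1):
        rule_name, mol = seen[can]
        metabolites.append(
            Molecule(
                id=f"{m.id}::M{i:02d}",
                smiles=can,
                canonical_form=can,
                heavy_atom_count=mol.GetNumHeavyAtoms(),
                role="metabolite",
                parent_id=m.id,
                rule=rule_name,
                _mol=mol,
            )
        )
    return metabolites


# ---------------------------------------------------------------------------
# rule I/O

_RULE_COLUMNS = ["name", "phase", "reactant_pattern", "transformation", "max_applications"]


def load_rules(path: str | Path) -> list[MetabolicRule]:
    """Load biotransformation rules from a TSV file.

    Columns: name, phase, reactant_pattern (SMARTS), transformation (reaction
    SMARTS), max_applications.
    """
    rules = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_RULE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"rule file missing columns: {sorted(missing)}")
        for row in reader:
            rules.append(
                MetabolicRule(
                    name=row["name"],
                    phase=row["phase"],
                    reactant_pattern=row["reactant_pattern"],
                    transformation=row["transformation"],
                    max_applications=int(row["max_applications"]),
                )
            )
    if not rules:
        raise FormatError(f"rule file {path} contains no rules")
    return rules


def default_rules() -> list[MetabolicRule]:
    """The shipped default rule set (phase-I hydrolytic and oxidative rules)."""
    ref = resources.files("drugscout.data") / "default_rules.tsv"
    with resources.as_file(ref) as path:
        return load_rules(path)


def read_smiles_file(path: str | Path) -> list[Molecule]:
    """Read a .smi file: one ``SMILES<TAB>id`` per line; '#' lines ignored."""
    molecules = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'SMILES<TAB>id', got {line!r}"
                )
            smiles, mol_id = parts
            molecules.append(parse_structure(mol_id, smiles))
    return molecules


def write_smiles_file(path: str | Path, molecules: Iterable[Molecule]) -> None:
    with open(path, "w") as fh:
        for m in molecules:
            fh.write(f"{m.smiles}\t{m.id}\n")
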
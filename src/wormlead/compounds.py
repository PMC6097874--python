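"""Compound data model, structure I/O and similarity operators.

Structures are held as canonical SMILES (RDKit canonicalisation) and all
similarity work runs on bit-set fingerprints, so two compounds entered with
different but equivalent SMILES compare identically.  The packaged fixture
library transcribes the 18 succinimide-related screening compounds
(ethosuximide, succinimide, MPS, methsuximide, ...) with per-compound
predicted aqueous log-solubility (LogS) values.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .errors import (
    ComparisonError,
    ComputationError,
    ConfigError,
    StructureError,
    ValidationError,
)

RDLogger.DisableLog("rdApp.*")  # parse failures are reported as exceptions, not stderr noise

DEFAULT_FP_KIND = "rdkit-path"
DEFAULT_FP_NBITS = 1024

# crude class-based pKa assignments for the most basic centre
_BASIC_AMINE = Chem.MolFromSmarts("[NX3;!$(N-C=O);!$(N-S=O);!$(N-C=N);!$(n);!$(N=*)]")
_ANILINE = Chem.MolFromSmarts("[NX3;!$(N-C=O);!$(N=*)]c")
_PKA_ALIPHATIC_AMINE = 10.0
_PKA_ANILINE = 4.6

SUCCINIMIDE_CORE = "O=C1CCC(=O)N1"  # pyrrolidine-2,5-dione ring
PYRROLIDINONE_CORE = "O=C1CCCN1"


@dataclass(frozen=True)
class Compound:
    """A named structure; ``smiles`` is always in canonical form."""

    id: str
    name: str
    smiles: str
    source: str = "user"
    logs: float | None = None  # configured predicted log10 solubility (mol/L)
    meta: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class DescriptorSet:
    """Physicochemical attributes feeding the CNS MPO and accumulation scores.

    ``clogd`` equals ``clogp`` for molecules with no basic centre at pH 7.4;
    otherwise a single-centre Henderson-Hasselbalch correction is applied.
    ``pka_basic`` is ``None`` when no basic nitrogen is present (imide and
    amide N-H are not basic centres).
    """

    mw: float
    clogp: float
    clogd: float
    tpsa: float
    hbd: int
    pka_basic: float | None
    logs: float
    rotatable_bonds: int


@dataclass(frozen=True)
class Fingerprint:
    kind: str
    nbits: int
    bits: frozenset[int]


def _mol_from_smiles(smiles: str, cid: str) -> Chem.Mol:
    if not smiles:
        raise StructureError(f"{cid}: empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"{cid}: unparsable SMILES {smiles!r}")
    return mol


def parse_compound(
    smiles: str, id: str, name: str, *, source: str = "user", logs: float | None = None
) -> Compound:
    """Parse and canonicalise a SMILES string into a :class:`Compound`.

    Raises :class:`StructureError` for unparsable, multi-fragment or charged
    input, naming the offending id.
    """
    mol = _mol_from_smiles(smiles, id)
    if len(Chem.GetMolFrags(mol)) != 1:
        raise StructureError(f"{id}: multi-fragment structure {smiles!r}")
    if Chem.GetFormalCharge(mol) != 0:
        raise StructureError(f"{id}: non-neutral structure {smiles!r}")
    return Compound(id=id, name=name, smiles=Chem.MolToSmiles(mol), source=source, logs=logs)


def estimate_logs(c: Compound) -> float:
    """Crude aqueous log-solubility estimate (ESOL-style linear model).

    Fallback used when a compound carries no configured LogS value; the
    fixture library ships frozen values produced by this estimator.
    """
    mol = _mol_from_smiles(c.smiles, c.id)
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    rb = rdMolDescriptors.CalcNumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    ap = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()) / heavy if heavy else 0.0
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


def _most_basic_pka(mol: Chem.Mol) -> float | None:
    """Class-based pKa of the most basic nitrogen, or None when not basic.

    Amide/imide nitrogens and aromatic ring nitrogens are excluded; anilines
    are treated as weakly basic, other sp3 amines as strong bases.
    """
    if mol.HasSubstructMatch(_BASIC_AMINE):
        if mol.HasSubstructMatch(_ANILINE):
            return _PKA_ANILINE
        return _PKA_ALIPHATIC_AMINE
    return None


def compute_descriptors(c: Compound) -> DescriptorSet:
    """Compute the descriptor set for one compound.

    Raises :class:`ComputationError` carrying the compound id if the
    underlying descriptor engine fails.
    """
    try:
        mol = _mol_from_smiles(c.smiles, c.id)
        mw = Descriptors.MolWt(mol)
        clogp = Crippen.MolLogP(mol)
        tpsa = rdMolDescriptors.CalcTPSA(mol)
        hbd = rdMolDescriptors.CalcNumHBD(mol)
        rb = rdMolDescriptors.CalcNumRotatableBonds(mol)
    except StructureError:
        raise
    except Exception as exc:  # pragma: no cover - engine failure path
        raise ComputationError(f"descriptor engine failed for {c.id}: {exc}") from exc
    pka = _most_basic_pka(mol)
    if pka is None:
        clogd = clogp
    else:
        # fraction neutral at pH 7.4 for a monobasic centre
        clogd = clogp - math.log10(1.0 + 10.0 ** (pka - 7.4))
    logs = c.logs if c.logs is not None else estimate_logs(c)
    return DescriptorSet(
        mw=mw, clogp=clogp, clogd=clogd, tpsa=tpsa, hbd=hbd,
        pka_basic=pka, logs=logs, rotatable_bonds=rb,
    )


def fingerprint(c: Compound, kind: str = DEFAULT_FP_KIND, nbits: int = DEFAULT_FP_NBITS) -> Fingerprint:
    """Bit-set fingerprint of a compound.

    ``rdkit-path`` (the default, a path-based fingerprint) and ``morgan``
    (radius-2 circular) are supported; anything else raises
    :class:`ConfigError`.
    """
    mol = _mol_from_smiles(c.smiles, c.id)
    if kind == "rdkit-path":
        bv = Chem.RDKFingerprint(mol, fpSize=nbits)
    elif kind == "morgan":
        bv = rdMolDescriptors.GetMorganFingerprintAsBitVect(mol, 2, nBits=nbits)
    else:
        raise ConfigError(f"unsupported fingerprint kind {kind!r}")
    return Fingerprint(kind=kind, nbits=nbits, bits=frozenset(bv.GetOnBits()))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| between two bit sets.

    Both-empty bit sets are defined to have similarity 0.
    """
    if a.kind != b.kind or a.nbits != b.nbits:
        raise ComparisonError(
            f"incomparable fingerprints: {a.kind}/{a.nbits} vs {b.kind}/{b.nbits}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def has_substructure(target: Compound, query: Compound | str) -> bool:
    """True iff ``query`` (a Compound or SMARTS/SMILES string) matches a subgraph of ``target``."""
    tmol = _mol_from_smiles(target.smiles, target.id)
    if isinstance(query, Compound):
        qmol = _mol_from_smiles(query.smiles, query.id)
    else:
        qmol = Chem.MolFromSmarts(query)
        if qmol is None:
            raise StructureError(f"unparsable query pattern {query!r}")
    return tmol.HasSubstructMatch(qmol)


# ---------------------------------------------------------------------------
# library I/O


def _check_ids(compounds: Sequence[Compound]) -> None:
    seen: set[str] = set()
    for c in compounds:
        if c.id in seen:
            raise ValidationError(f"duplicate compound id {c.id!r}")
        seen.add(c.id)
    if not compounds:
        raise ValidationError("empty compound library")


def load_library(path: str | Path, format: str | None = None) -> list[Compound]:
    """Read a compound library from .smi, .sdf or .csv.

    CSV requires the header ``id,name,smiles`` with an optional ``logs``
    column; .smi is ``smiles<TAB>id`` per line.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    compounds: list[Compound] = []
    if fmt == "smi":
        for i, line in enumerate(path.read_text().splitlines()):
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"line{i + 1}"
            compounds.append(parse_compound(smiles, cid, cid))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                raise StructureError(f"unparsable SDF record {i + 1} in {path}")
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"rec{i + 1}"
            name = mol.GetProp("name") if mol.HasProp("name") else cid
            logs = float(mol.GetProp("logs")) if mol.HasProp("logs") else None
            compounds.append(parse_compound(Chem.MolToSmiles(mol), cid, name, logs=logs))
    elif fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            cols = reader.fieldnames or []
            for required in ("id", "name", "smiles"):
                if required not in cols:
                    raise ValidationError(f"{path}: missing column {required!r}")
            for row in reader:
                logs = float(row["logs"]) if row.get("logs") not in (None, "") else None
                meta = {
                    k: row[k]
                    for k in cols
                    if k not in ("id", "name", "smiles", "logs") and row.get(k)
                }
                c = parse_compound(row["smiles"], row["id"], row["name"], logs=logs)
                compounds.append(replace(c, meta=meta))
    else:
        raise ConfigError(f"unsupported library format {fmt!r}")
    _check_ids(compounds)
    return compounds


def write_library(compounds: Sequence[Compound], path: str | Path, format: str | None = None) -> None:
    """Write a library; canonical SMILES are emitted. Inverse of :func:`load_library`."""
    _check_ids(list(compounds))
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "smi":
        path.write_text("".join(f"{c.smiles}\t{c.id}\n" for c in compounds))
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        for c in compounds:
            mol = _mol_from_smiles(c.smiles, c.id)
            mol.SetProp("_Name", c.id)
            mol.SetProp("name", c.name)
            if c.logs is not None:
                mol.SetProp("logs", repr(c.logs))
            writer.write(mol)
        writer.close()
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "name", "smiles", "logs"])
            for c in compounds:
                writer.writerow([c.id, c.name, c.smiles, "" if c.logs is None else c.logs])
    else:
        raise ConfigError(f"unsupported library format {fmt!r}")


def fixture_library() -> list[Compound]:
    """The packaged 18-compound screening library (returns exactly 18 compounds)."""
    with resources.as_file(
        resources.files("wormlead.data").joinpath("fixture_compounds.csv")
    ) as p:
        lib = load_library(p, "csv")
    out = []
    for c in lib:
        out.append(replace(c, source="fixture"))
    return out


def get_compound(library: Iterable[Compound], key: str) -> Compound:
    """Look a compound up by id or (case-insensitive) name."""
    for c in library:
        if c.id == key or c.name.lower() == key.lower():
            return c
    raise ValidationError(f"compound {key!r} not in library")
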
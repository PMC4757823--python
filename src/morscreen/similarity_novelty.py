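"""Circular-fingerprint Tanimoto novelty assessment of screening hits.

Uses a conventional ECFP4 analogue: Morgan fingerprints of radius 2 folded
to 2048 bits.  A query compound's novelty against a reference set (e.g. the
known actives a model was trained on) is summarised by its nearest
reference (maximum Tanimoto) and by the mean Tanimoto over all
query-reference pairs; a low maximum Tanimoto flags a novel scaffold.
Absolute values depend on the hashing scheme, so cross-package fingerprint
values are not comparable bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .errors import DomainError
from .library_io import Compound

DEFAULT_RADIUS = 2
DEFAULT_NBITS = 2048


@dataclass(frozen=True)
class Fingerprint:
    """A folded circular fingerprint: the set of on-bits plus its parameters."""

    bits: frozenset
    radius: int = DEFAULT_RADIUS
    nbits: int = DEFAULT_NBITS

    @property
    def params(self) -> tuple[int, int]:
        return (self.radius, self.nbits)


def circular_fingerprint(
    compound: Compound | Chem.Mol,
    radius: int = DEFAULT_RADIUS,
    nbits: int = DEFAULT_NBITS,
) -> Fingerprint:
    """Morgan (ECFP-style) fingerprint of a molecule, counts folded to bits."""
    mol = compound.mol if isinstance(compound, Compound) else compound
    if mol is None or mol.GetNumAtoms() == 0:
        raise DomainError("cannot fingerprint an empty molecule")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), radius=radius, nbits=nbits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a & b| / |a | b|; undefined when both are empty."""
    if a.params != b.params:
        raise DomainError(f"fingerprint parameter mismatch: {a.params} vs {b.params}")
    union = a.bits | b.bits
    if not union:
        raise DomainError("Tanimoto of two empty fingerprints is undefined")
    return len(a.bits & b.bits) / len(union)


@dataclass(frozen=True)
class NoveltyReport:
    """Per-query nearest reference and overall library similarity."""

    per_query: tuple[tuple[str, str, float], ...]  # (query_id, nearest_ref_id, max_Tc)
    overall_similarity: float  # mean Tc over all query x reference pairs
    overall_nearest_neighbor: float  # mean of per-query max Tc (alternative)

    def max_tc(self, query_id: str) -> float:
        for qid, _, tc in self.per_query:
            if qid == query_id:
                return tc
        raise KeyError(query_id)

    def nearest_reference(self, query_id: str) -> str:
        for qid, ref, _ in self.per_query:
            if qid == query_id:
                return ref
        raise KeyError(query_id)


def compare_libraries(
    queries: dict[str, Fingerprint],
    references: dict[str, Fingerprint],
) -> NoveltyReport:
    """Nearest-reference similarity of every query against a reference library.

    Ties on the maximum Tanimoto resolve to the lexicographically smallest
    reference id.  ``overall_similarity`` is the mean over all pairs;
    the nearest-neighbor mean is reported alongside as the alternative
    convention.
    """
    if not queries or not references:
        raise DomainError("both query and reference sets must be non-empty")
    per_query = []
    all_tc = []
    for qid in sorted(queries):
        best_ref, best_tc = None, -1.0
        for rid in sorted(references):
            tc = tanimoto(queries[qid], references[rid])
            all_tc.append(tc)
            if tc > best_tc:
                best_ref, best_tc = rid, tc
        per_query.append((qid, best_ref, best_tc))
    nn_mean = sum(tc for _, _, tc in per_query) / len(per_query)
    return NoveltyReport(
        per_query=tuple(per_query),
        overall_similarity=sum(all_tc) / len(all_tc),
        overall_nearest_neighbor=nn_mean,
    )


def compare_smiles_libraries(
    query_smiles: dict[str, str], reference_smiles: dict[str, str]
) -> NoveltyReport:
    """Convenience wrapper fingerprinting SMILES dicts before comparison."""
    def fps(d: dict[str, str]) -> dict[str, Fingerprint]:
        out = {}
        for cid, smi in d.items():
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise DomainError(f"unparsable SMILES for {cid!r}")
            out[cid] = circular_fingerprint(mol)
        return out

    return compare_libraries(fps(query_smiles), fps(reference_smiles))
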
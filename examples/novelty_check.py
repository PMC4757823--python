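"""Fingerprint novelty of screening hits against a known-actives library.

Computes ECFP4-style circular fingerprints (Morgan radius 2, 2048 bits) and
reports, for each query, the most similar reference compound (maximum
Tanimoto) and the mean similarity over all pairs.  A low maximum Tanimoto
(well below ~0.4) indicates a scaffold absent from the reference set.
"""

from morscreen import compare_smiles_libraries

# two hypothetical screening hits vs a small morphinan-flavoured reference set
report = compare_smiles_libraries(
    {
        # a tetrahydroisoquinoline (laudanosine-like) and a benzenesulfonamide
        "hit-1": "COc1ccc2c(c1OC)C(Cc1ccc(OC)c(OC)c1)N(C)CC2",
        "hit-2": "NS(=O)(=O)c1ccc(C(=O)Nc2ccccn2)cc1",
    },
    {
        "ref-morphine": "CN1CC[C@]23c4c5ccc(O)c4O[C@H]2[C@@H](O)C=C[C@H]3[C@H]1C5",
        "ref-morphinone": "CN1CCC23c4c5ccc(O)c4OC2C(=O)CCC3C1C5",
        "ref-fentanyl": "CCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1",
    },
)
for qid, ref, tc in report.per_query:
    print(f"{qid}: nearest reference {ref}, max Tc = {tc:.3f}")
print(f"overall similarity (mean over all pairs) = {report.overall_similarity:.4f}")
print()
print("Tc = 1 would mean an identical compound; values near 0.2 flag novel chemotypes.")
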
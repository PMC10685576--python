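"""Optional chemistry backend: SMILES -> pharmacophoric feature graph.

Requires RDKit.  Feature detection uses RDKit's chemical-feature factory
(``BaseFeatures.fdef``) by default, mapping its families onto the six
feature codes:

    Acceptor -> A, Donor -> D, NegIonizable -> N, PosIonizable -> P,
    Hydrophobe -> H, Aromatic -> R

A multi-atom feature (ring, hydrophobic patch) is anchored at its
lowest-index atom so distances stay integral and reproducible; pairwise
feature distances are shortest bond-path lengths (bond counts), with
pairs on different fragments marked unreachable.  Custom feature rules
may be supplied as a mapping {code: [SMARTS, ...]}; the first matched
atom of each SMARTS hit is the anchor.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .model import MoleculeRecord

try:  # pragma: no cover - exercised only when rdkit is present
    from rdkit import Chem, RDConfig
    from rdkit.Chem import ChemicalFeatures

    _HAVE_RDKIT = True
except ImportError:  # pragma: no cover
    _HAVE_RDKIT = False

_FAMILY_TO_CODE = {
    "Acceptor": "A",
    "Donor": "D",
    "NegIonizable": "N",
    "PosIonizable": "P",
    "Hydrophobe": "H",
    "Aromatic": "R",
}

_factory = None


def _default_factory():
    global _factory
    if _factory is None:
        import os

        _factory = ChemicalFeatures.BuildFeatureFactory(
            os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
        )
    return _factory


def featurize_smiles(
    mol_id: str,
    smiles: str,
    activity_value: float | None = None,
    feature_rules: Mapping[str, Sequence[str]] | None = None,
) -> MoleculeRecord:
    """Annotate one SMILES as a feature graph.

    ``feature_rules`` optionally replaces the default feature factory
    with per-code SMARTS lists.
    """
    if not _HAVE_RDKIT:
        raise ImportError(
            "the SMILES reader needs the optional chemistry backend; "
            "install the 'chem' extra (rdkit)"
        )
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"molecule {mol_id}: invalid SMILES {smiles!r}")

    anchors: set[tuple[str, int]] = set()
    if feature_rules is None:
        for feat in _default_factory().GetFeaturesForMol(mol):
            code = _FAMILY_TO_CODE.get(feat.GetFamily())
            if code is None:
                continue
            anchors.add((code, min(feat.GetAtomIds())))
    else:
        for code, patterns in feature_rules.items():
            for smarts in patterns:
                patt = Chem.MolFromSmarts(smarts)
                if patt is None:
                    raise ValueError(f"invalid SMARTS {smarts!r} for code {code}")
                for match in mol.GetSubstructMatches(patt):
                    anchors.add((code, match[0]))

    features = sorted(anchors, key=lambda t: (t[1], t[0]))
    dmat = Chem.GetDistanceMatrix(mol)
    n = len(features)
    dist: list[list[int | None]] = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            d = dmat[features[i][1]][features[j][1]]
            dist[i][j] = None if d >= 1e8 else int(d)  # 1e8: rdkit's "no path"
    return MoleculeRecord(
        mol_id, tuple(features), tuple(map(tuple, dist)), activity_value=activity_value
    )
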
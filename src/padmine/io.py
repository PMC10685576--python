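"""Readers and writers for the dataset interchange and report formats.

The primary dataset format is the *feature-graph JSON* dialect::

    {
      "activity_cutoff": 100.0,
      "molecules": [
        {
          "id": "mol1",
          "activity_nM": 42.0,            # optional; null for unlabeled
          "features": [{"kind": "A", "anchor": 0}, ...],
          "dist": [[0, 2, ...], ...]      # symmetric; null = unreachable
        },
        ...
      ]
    }

A SMILES TSV reader (columns: id, SMILES, activity_nM) is available when
the optional chemistry backend is installed; see :mod:`padmine.chem`.
"""

from __future__ import annotations

import json
from typing import Iterable

import pandas as pd

from .equivalence import EquivalenceClass
from .mining import SupportIndex
from .model import Dataset, MoleculeRecord
from .network import PharmNetwork
from .quality import PertinenceRecord
from .stability import StabilityReport

__all__ = [
    "load_feature_graph_json",
    "dump_feature_graph_json",
    "read_smiles_tsv",
    "write_pharmacophores_tsv",
    "write_ec_tsv",
    "write_pad_tsv",
    "write_stability_tsv",
]


def load_feature_graph_json(path, activity_cutoff: float | None = None) -> Dataset:
    """Load a dataset from the feature-graph JSON dialect.

    ``activity_cutoff`` overrides the value stored in the file (default
    100 nM when neither is given).
    """
    with open(path) as fh:
        data = json.load(fh)
    cutoff = activity_cutoff if activity_cutoff is not None else data.get("activity_cutoff", 100.0)
    molecules = []
    for entry in data["molecules"]:
        dist = tuple(
            tuple(None if d is None else int(d) for d in row) for row in entry["dist"]
        )
        molecules.append(
            MoleculeRecord(
                id=str(entry["id"]),
                features=tuple((f["kind"], int(f["anchor"])) for f in entry["features"]),
                dist=dist,
                activity_value=(
                    None if entry.get("activity_nM") is None else float(entry["activity_nM"])
                ),
            )
        )
    return Dataset(molecules, cutoff)


def dump_feature_graph_json(dataset: Dataset, path) -> None:
    data = {
        "activity_cutoff": dataset.activity_cutoff,
        "molecules": [
            {
                "id": m.id,
                "activity_nM": m.activity_value,
                "features": [{"kind": k, "anchor": a} for k, a in m.features],
                "dist": [list(row) for row in m.dist],
            }
            for m in dataset
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def read_smiles_tsv(path, activity_cutoff: float = 100.0, feature_rules=None) -> Dataset:
    """Read an (id, SMILES, activity_nM) TSV through the chemistry
    backend.  Requires the optional ``rdkit`` dependency."""
    from .chem import featurize_smiles  # deferred: rdkit is optional

    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = [c.lower() for c in df.columns]
    try:
        id_col = df.columns[cols.index("id")]
        smi_col = df.columns[cols.index("smiles")]
        act_col = df.columns[cols.index("activity_nm")]
    except ValueError as exc:
        raise ValueError("SMILES TSV needs columns: id, SMILES, activity_nM") from exc
    molecules = []
    for _, row in df.iterrows():
        value = row[act_col]
        molecules.append(
            featurize_smiles(
                str(row[id_col]),
                str(row[smi_col]),
                activity_value=None if pd.isna(value) else float(value),
                feature_rules=feature_rules,
            )
        )
    return Dataset(molecules, activity_cutoff)


def write_pharmacophores_tsv(index: SupportIndex, path) -> None:
    """One row per mined pharmacophore: notation, order, support size,
    semicolon-joined support ids."""
    rows = []
    for key in index.notations():
        p, supp = index.entries[key]
        rows.append(
            {
                "notation": key,
                "order": p.order,
                "support_size": len(supp),
                "support_ids": ";".join(sorted(supp)),
            }
        )
    pd.DataFrame(rows, columns=["notation", "order", "support_size", "support_ids"]).to_csv(
        path, sep="\t", index=False
    )


def write_ec_tsv(ecs: Iterable[EquivalenceClass], path) -> None:
    rows = [
        {
            "kind": ec.kind,
            "representative": ec.representative,
            "order": ec.representative_order,
            "n_members": len(ec.members),
            "n_generators": len(ec.generators),
            "n_closed": len(ec.closed),
            "support_size": len(ec.support),
        }
        for ec in ecs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "kind",
            "representative",
            "order",
            "n_members",
            "n_generators",
            "n_closed",
            "support_size",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_pad_tsv(records: Iterable[PertinenceRecord], net: PharmNetwork, path) -> None:
    """Per-vertex quality report: GR_N, sibling statistics, pertinence
    and the PAD flag."""
    rows = []
    for r in records:
        payload = net.payload(r.vertex)
        order = getattr(payload, "representative_order", None) or getattr(
            payload, "order", None
        )
        rows.append(
            {
                "vertex": r.vertex,
                "order": order,
                "support_size": len(net.support(r.vertex)),
                "gr_n": r.quality,
                "card_siblings": r.card_siblings,
                "mu": r.mu,
                "sigma": r.sigma,
                "pertinence": r.pertinence,
                "is_pad": r.is_pad,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "vertex",
            "order",
            "support_size",
            "gr_n",
            "card_siblings",
            "mu",
            "sigma",
            "pertinence",
            "is_pad",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_stability_tsv(report: StabilityReport, path) -> None:
    """Two blocks: per-fold stage counts, then cumulative PAD presence
    for m = k down to 1 against the chance baseline."""
    with open(path, "w") as fh:
        fh.write("fold\tn_pharmacophores\tn_secs\tn_pads_pos\tn_pads_neg\n")
        for i, (np_, ns, pp, pn) in enumerate(report.per_fold, start=1):
            fh.write(f"F{i}\t{np_}\t{ns}\t{pp}\t{pn}\n")
        fh.write("\n")
        fh.write("at_least_m_folds\tn_pads_pos\tn_pads_neg\tchance_baseline\n")
        for m in range(report.n_folds, 0, -1):
            fh.write(
                f"{m}\t{report.cumulative_pos.get(m, 0)}\t"
                f"{report.cumulative_neg.get(m, 0)}\t"
                f"{report.chance_curve[m]:.5f}\n"
            )
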
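"""Readers and writers for the tabular interchange formats.

Drug tables and DDI edge lists are CSV or TSV with headers
(``drug_id,smiles`` and ``drug_id_1,drug_id_2[,label]``; a missing label
column means every listed pair interacts). Pretraining corpora are
one-SMILES-per-line ``.smi`` files. Split assignments and predictions
are written as TSV.
"""

from __future__ import annotations

import pandas as pd

from .chem_graph import DDINetwork, SplitAssignment


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_drug_table(path) -> list[tuple[str, str]]:
    df = _read_table(path)
    if not {"drug_id", "smiles"} <= set(df.columns):
        raise ValueError("drug table needs columns drug_id,smiles")
    return list(zip(df["drug_id"].astype(str), df["smiles"].astype(str)))


def read_edge_list(path) -> list[tuple]:
    df = _read_table(path)
    if not {"drug_id_1", "drug_id_2"} <= set(df.columns):
        raise ValueError("edge list needs columns drug_id_1,drug_id_2[,label]")
    if "label" in df.columns:
        return list(
            zip(df["drug_id_1"].astype(str), df["drug_id_2"].astype(str), df["label"].astype(int))
        )
    return list(zip(df["drug_id_1"].astype(str), df["drug_id_2"].astype(str)))


def read_smiles_corpus(path) -> list[str]:
    with open(path) as fh:
        return [line.split()[0] for line in fh if line.strip()]


def write_smiles_corpus(path, smiles: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(smiles) + "\n")


def write_drug_table(path, drugs: list[tuple[str, str]]) -> None:
    pd.DataFrame(drugs, columns=["drug_id", "smiles"]).to_csv(path, index=False)


def write_edge_list(path, network: DDINetwork) -> None:
    rows = [
        (network.drug_ids[i], network.drug_ids[j], y) for i, j, y in network.labeled_pairs
    ]
    pd.DataFrame(rows, columns=["drug_id_1", "drug_id_2", "label"]).to_csv(path, index=False)


def write_split_assignment(drug_path, link_path, assignment: SplitAssignment, network: DDINetwork) -> None:
    pd.DataFrame(
        sorted(assignment.drug_split.items()), columns=["drug_id", "split"]
    ).to_csv(drug_path, sep="\t", index=False)
    label_of = {(i, j): y for i, j, y in network.labeled_pairs}
    rows = [
        (network.drug_ids[i], network.drug_ids[j], label_of[(i, j)], s)
        for (i, j), s in sorted(assignment.link_split.items())
    ]
    pd.DataFrame(rows, columns=["drug_id_1", "drug_id_2", "label", "split"]).to_csv(
        link_path, sep="\t", index=False
    )


def write_predictions(path, network: DDINetwork, pairs, scores) -> None:
    rows = [
        (network.drug_ids[i], network.drug_ids[j], float(s))
        for (i, j), s in zip(pairs, scores)
    ]
    pd.DataFrame(rows, columns=["drug_id_1", "drug_id_2", "prob_interaction"]).to_csv(
        path, sep="\t", index=False
    )
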
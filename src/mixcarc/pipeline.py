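"""End-to-end dataset assembly: chemicals -> labeled pairs -> model inputs.

Ties the library together for the three tasks:

* binary — carcinogen pairs labeled under Case 1 (1+1=1), noncarcinogen
  pairs under Case 2 (0+0=0);
* multiclass — intraclass pairs, the mixture inheriting the shared class;
* regression — pairs of TD50-annotated carcinogens under the equitoxic CA
  construction: concentration fractions from TD50 weights, mixture TD50 as
  the component average, target ``-log10 TD50_mix``.

Concentration fractions weight the mixture descriptors. Classification
pairs use exposure-concentration weights when both components carry one and
equal fractions (0.5/0.5) otherwise; regression pairs always use the
CA-derived TD50 weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import ca
from .chem import ChemicalRecord
from .descriptors import (
    DescriptorMatrix,
    compute_single_descriptors,
    filter_complete,
    mixture_feature_table,
)
from .mixtures import MixturePair, enumerate_pairs, make_pair
from .models import pack_hybrid_input
from .smiles import DEFAULT_LENGTH, concat_mixture_smiles, encode_batch


def _fractions(rec_a: ChemicalRecord, rec_b: ChemicalRecord) -> float:
    """Concentration fraction x_a for a classification pair."""
    if rec_a.concentration is not None and rec_b.concentration is not None:
        x_a, _ = ca.concentration_fractions(rec_a.concentration, rec_b.concentration)
        return x_a
    return 0.5


def label_binary_pairs(records: list[ChemicalRecord]) -> list[MixturePair]:
    """Case 1 pairs among carcinogens plus Case 2 pairs among noncarcinogens."""
    by_id = {r.chem_id: r for r in records}
    carcinogens = [r for r in records if r.binary_label == 1]
    noncarcinogens = [r for r in records if r.binary_label == 0]
    out: list[MixturePair] = []
    for group, case, label in ((carcinogens, 1, 1), (noncarcinogens, 2, 0)):
        if len(group) < 2:
            continue
        for p in enumerate_pairs(group):
            ra, rb = by_id[p.chem_a], by_id[p.chem_b]
            out.append(
                make_pair(
                    p.chem_a,
                    p.chem_b,
                    x_a=_fractions(ra, rb),
                    binary_label=label,
                    assumption_case=case,
                )
            )
    return out


def label_multiclass_pairs(records: list[ChemicalRecord]) -> list[MixturePair]:
    """Intraclass pairs with equal concentrations, labeled by the shared class."""
    out: list[MixturePair] = []
    for cls in (0, 1, 2):
        members = [r for r in records if r.class_label == cls]
        if len(members) < 2:
            continue
        for p in enumerate_pairs(members):
            out.append(replace(p, class_label=cls))
    return out


def label_regression_pairs(records: list[ChemicalRecord]) -> list[MixturePair]:
    """Equitoxic CA pairs among TD50-annotated carcinogens."""
    annotated = {r.chem_id: r for r in records if r.td50 is not None}
    out: list[MixturePair] = []
    if len(annotated) < 2:
        return out
    for p in enumerate_pairs(list(annotated.values())):
        chain = ca.ca_chain(annotated[p.chem_a].td50, annotated[p.chem_b].td50)
        out.append(
            make_pair(
                p.chem_a,
                p.chem_b,
                x_a=chain.p_a,
                binary_label=1,
                td50_mix=chain.td50_mix,
                assumption_case=1,
            )
        )
    return out


def label_pairs(records: list[ChemicalRecord], task: str) -> list[MixturePair]:
    if task == "binary":
        return label_binary_pairs(records)
    if task == "multiclass":
        return label_multiclass_pairs(records)
    if task == "regression":
        return label_regression_pairs(records)
    raise ValueError(f"unknown task {task!r}")


@dataclass
class MixtureDataset:
    """Assembled model inputs for one task."""

    task: str
    pairs: list
    X: np.ndarray  # packed: smiles tokens (first L cols) then descriptors
    y: np.ndarray
    smiles_length: int
    descriptor_names: list

    @property
    def pair_ids(self) -> list[str]:
        return [f"{p.chem_a}|{p.chem_b}" for p in self.pairs]

    def chem_ids(self) -> set[str]:
        return {cid for p in self.pairs for cid in (p.chem_a, p.chem_b)}


def targets_for(pairs: list[MixturePair], task: str) -> np.ndarray:
    if task == "binary":
        vals = [p.binary_label for p in pairs]
    elif task == "multiclass":
        vals = [p.class_label for p in pairs]
    else:
        vals = [ca.regression_target(p.td50_mix) if p.td50_mix is not None else None for p in pairs]
    if any(v is None for v in vals):
        raise ValueError(f"some pairs lack the {task} target")
    return np.asarray(vals, dtype=float if task == "regression" else int)


def featurize_pairs(
    pairs: list[MixturePair],
    records: list[ChemicalRecord],
    method: str = "sum",
    smiles_length: int = DEFAULT_LENGTH,
    descriptor_matrix: DescriptorMatrix | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Packed (tokens + mixture descriptors) feature matrix for pairs."""
    by_id = {r.chem_id: r for r in records}
    if descriptor_matrix is None:
        descriptor_matrix = filter_complete(compute_single_descriptors(records))
    feats = mixture_feature_table(pairs, descriptor_matrix, method=method)
    tokens = None
    if smiles_length:
        mix_smiles = [
            concat_mixture_smiles(by_id[p.chem_a].smiles, by_id[p.chem_b].smiles)
            for p in pairs
        ]
        tokens = encode_batch(mix_smiles, smiles_length)
    X = pack_hybrid_input(tokens, feats.values)
    return X, list(feats.columns)


def build_dataset(
    records: list[ChemicalRecord],
    task: str,
    method: str = "sum",
    smiles_length: int = DEFAULT_LENGTH,
    pairs: list[MixturePair] | None = None,
) -> MixtureDataset:
    """Assemble a ready-to-fit dataset for a task from single chemicals."""
    if pairs is None:
        pairs = label_pairs(records, task)
    if not pairs:
        raise ValueError(f"no pairs could be formed for task {task!r}")
    X, names = featurize_pairs(pairs, records, method=method, smiles_length=smiles_length)
    return MixtureDataset(
        task=task,
        pairs=pairs,
        X=X,
        y=targets_for(pairs, task),
        smiles_length=smiles_length,
        descriptor_names=names,
    )


def pairs_frame(pairs: list[MixturePair], split: str | None = None) -> pd.DataFrame:
    from .mixtures import pairs_to_rows

    return pd.DataFrame(pairs_to_rows(pairs, split=split))
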
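"""Per-chemical 2D descriptors and dose-weighted mixture descriptors.

Single chemicals are featurized with RDKit's 2D descriptor set; columns with
any missing or non-finite value across the library are dropped so the
retained matrix is fully finite (the retained count is engine- and
dataset-dependent — the completeness rule, not the count, is the contract).
A mixture's descriptor vector D combines the two component vectors d1, d2
weighted by their concentration fractions x1, x2:

    sum:        D = x1*d1 + x2*d2
    difference: D = |x1*d1 - x2*d2|
    norm:       D = sqrt((x1*d1)^2 + (x2*d2)^2)

all elementwise. The sum method is the default throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyFeatureError
from .mixtures import FRACTION_TOL, MixturePair

METHODS = ("sum", "difference", "norm")


@dataclass
class DescriptorMatrix:
    """Finite-valued chemicals x descriptors table.

    ``values`` rows follow ``chem_ids`` order; after :func:`filter_complete`
    the matrix contains no missing or non-finite entries. ``failures`` maps
    chemicals the engine could not featurize to the error message (those
    chemicals have no row).
    """

    chem_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    failures: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.chem_ids), len(self.descriptor_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.chem_ids)} chemicals x {len(self.descriptor_names)} descriptors"
            )

    def row(self, chem_id: str) -> np.ndarray:
        return self.values[self.chem_ids.index(chem_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.chem_ids, columns=self.descriptor_names)


def descriptor_names() -> list[str]:
    """Names of the configured 2D descriptor engine's columns."""
    from rdkit.Chem import Descriptors

    return [name for name, _ in Descriptors.descList]


def compute_single_descriptors(records: Sequence) -> DescriptorMatrix:
    """Compute the raw (pre-filter) 2D descriptor matrix, one row per chemical.

    Engine failure on a structure is recorded per chemical and the run
    continues; the raw matrix may contain missing values (NaN), which
    :func:`filter_complete` later removes column-wise.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    names = descriptor_names()
    ids: list[str] = []
    rows: list[np.ndarray] = []
    failures: dict[str, str] = {}
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            failures[rec.chem_id] = f"unparsable SMILES {rec.smiles!r}"
            continue
        row = np.empty(len(names))
        try:
            calc = Descriptors.CalcMolDescriptors(mol, missingVal=np.nan)
            for j, name in enumerate(names):
                row[j] = calc[name]
        except Exception as exc:  # engine failure on one structure
            failures[rec.chem_id] = str(exc)
            continue
        ids.append(rec.chem_id)
        rows.append(row)
    values = np.vstack(rows) if rows else np.zeros((0, len(names)))
    return DescriptorMatrix(chem_ids=ids, descriptor_names=names, values=values,
                            failures=failures)


def filter_complete(matrix: DescriptorMatrix) -> DescriptorMatrix:
    """Drop every column containing any missing or non-finite value.

    Idempotent; raises :class:`EmptyFeatureError` if nothing survives.
    """
    finite = np.isfinite(matrix.values)
    keep = finite.all(axis=0)
    if not keep.any():
        raise EmptyFeatureError("completeness filtering removed every descriptor column")
    names = [n for n, k in zip(matrix.descriptor_names, keep) if k]
    return DescriptorMatrix(
        chem_ids=list(matrix.chem_ids),
        descriptor_names=names,
        values=matrix.values[:, keep],
        failures=dict(matrix.failures),
    )


def mixture_descriptor(d1, d2, x1: float, x2: float, method: str = "sum") -> np.ndarray:
    """Dose-weighted mixture descriptor vector from two component vectors."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError(f"descriptor shape mismatch: {d1.shape} vs {d2.shape}")
    if abs(x1 + x2 - 1.0) > FRACTION_TOL:
        raise ValueError(f"fractions must sum to 1, got {x1} + {x2}")
    a, b = x1 * d1, x2 * d2
    if method == "sum":
        return a + b
    if method == "difference":
        return np.abs(a - b)
    if method == "norm":
        return np.sqrt(a * a + b * b)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def mixture_feature_table(
    pairs: Iterable[MixturePair],
    matrix: DescriptorMatrix,
    method: str = "sum",
) -> pd.DataFrame:
    """Featurize many pairs against a filtered descriptor matrix.

    Returns a DataFrame indexed by ``"chem_a|chem_b"`` with one column per
    retained descriptor.
    """
    index = {cid: i for i, cid in enumerate(matrix.chem_ids)}
    rows, labels = [], []
    for p in pairs:
        try:
            ia, ib = index[p.chem_a], index[p.chem_b]
        except KeyError as exc:
            raise KeyError(f"pair ({p.chem_a}, {p.chem_b}): no descriptor row for {exc.args[0]}") from None
        rows.append(mixture_descriptor(matrix.values[ia], matrix.values[ib], p.x_a, p.x_b, method))
        labels.append(f"{p.chem_a}|{p.chem_b}")
    values = np.vstack(rows) if rows else np.zeros((0, len(matrix.descriptor_names)))
    return pd.DataFrame(values, index=labels, columns=matrix.descriptor_names)
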
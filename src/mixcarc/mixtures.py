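"""Virtual binary-mixture generation.

Builds all C(n,2) unordered pairs from a single-chemical library, labels them
under the assumption cases (carcinogen + carcinogen = carcinogen, and so on),
splits chemicals into compound-disjoint train/test partitions before pairing,
and subsamples pair pools uniformly or stratified by Tanimoto similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import CaseMismatchError, InfeasibleSplitError, InterclassError

#: Tolerance on the concentration-fraction sum.
FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class MixturePair:
    """An unordered two-chemical mixture.

    Pairs are stored in canonical orientation (``chem_a < chem_b``
    lexicographically, fractions swapped along), so ``(a, b)`` and ``(b, a)``
    compare and hash equal. Concentration fractions are open-interval (0, 1)
    and sum to 1.
    """

    chem_a: str
    chem_b: str
    x_a: float = 0.5
    x_b: float = 0.5
    binary_label: int | None = None
    class_label: int | None = None
    td50_mix: float | None = None
    assumption_case: int | None = None

    def __post_init__(self):
        if self.chem_a == self.chem_b:
            raise ValueError(f"self-pair: {self.chem_a}")
        if self.chem_a > self.chem_b:  # canonical orientation, fractions follow their ids
            a, b, xa, xb = self.chem_b, self.chem_a, self.x_b, self.x_a
            object.__setattr__(self, "chem_a", a)
            object.__setattr__(self, "chem_b", b)
            object.__setattr__(self, "x_a", xa)
            object.__setattr__(self, "x_b", xb)
        if abs(self.x_a + self.x_b - 1.0) > FRACTION_TOL:
            raise ValueError(f"fractions must sum to 1: {self.x_a} + {self.x_b}")
        if not (0.0 < self.x_a < 1.0 and 0.0 < self.x_b < 1.0):
            raise ValueError("fractions must lie strictly inside (0, 1)")
        if self.td50_mix is not None and not self.td50_mix > 0:
            raise ValueError("td50_mix must be positive")
        if self.assumption_case is not None and self.assumption_case not in (1, 2, 3, 4, 5):
            raise ValueError("assumption_case must be in 1..5")

    @property
    def key(self) -> tuple[str, str]:
        return (self.chem_a, self.chem_b)


def make_pair(chem_a: str, chem_b: str, x_a: float = 0.5, **kwargs) -> MixturePair:
    """Construct a pair in canonical orientation, keeping fractions attached
    to the right component when the ids need swapping."""
    if chem_a == chem_b:
        raise ValueError(f"self-pair: {chem_a}")
    if chem_a > chem_b:
        chem_a, chem_b = chem_b, chem_a
        x_a = 1.0 - x_a
    return MixturePair(chem_a=chem_a, chem_b=chem_b, x_a=x_a, x_b=1.0 - x_a, **kwargs)


def _ids(chemicals: Sequence) -> list[str]:
    ids = [c.chem_id if hasattr(c, "chem_id") else str(c) for c in chemicals]
    if len(set(ids)) != len(ids):
        raise ValueError("chemical ids must be unique")
    return ids


def enumerate_pairs(chemicals: Sequence) -> list[MixturePair]:
    """All C(n,2) unordered pairs in canonical lexicographic order.

    Accepts :class:`~mixcarc.chem.ChemicalRecord` objects or plain id
    strings. Equal concentration fractions (0.5/0.5) are assigned; callers
    attach labels and CA-derived fractions afterwards.
    """
    ids = _ids(chemicals)
    if len(ids) < 2:
        raise ValueError("need at least 2 chemicals to form pairs")
    ids = sorted(ids)
    return [
        MixturePair(chem_a=ids[i], chem_b=ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    ]


#: Assumption cases: (required label pattern as an unordered check) -> mixture label.
#: Case 1: carcinogen + carcinogen -> carcinogen (1 + 1 = 1)
#: Case 2: noncarcinogen + noncarcinogen -> noncarcinogen (0 + 0 = 0)
#: Case 3: noncarcinogen + noncarcinogen -> carcinogen (0 + 0 = 1)
#: Case 4: carcinogen + noncarcinogen -> carcinogen (1 + 0 = 1)
#: Case 5: noncarcinogen + carcinogen -> carcinogen (0 + 1 = 1)
_CASES: dict[int, tuple[tuple[int, int], int]] = {
    1: ((1, 1), 1),
    2: ((0, 0), 0),
    3: ((0, 0), 1),
    4: ((1, 0), 1),
    5: ((0, 1), 1),
}


def label_by_case(label_a: int, label_b: int, case: int) -> int:
    """Mixture binary label under one assumption case.

    The component labels must match the pattern the case requires (Case 1
    needs 1,1; Cases 2-3 need 0,0; Case 4 needs 1,0; Case 5 needs 0,1),
    otherwise :class:`CaseMismatchError` is raised.
    """
    if case not in _CASES:
        raise ValueError(f"unknown assumption case {case}")
    pattern, result = _CASES[case]
    if (label_a, label_b) != pattern:
        raise CaseMismatchError(
            f"case {case} requires component labels {pattern}, got ({label_a}, {label_b})"
        )
    return result


def intraclass_label(class_a: int, class_b: int) -> int:
    """Multiclass mixture label: the shared class of the two components.

    Only intraclass mixtures are defined; mixing two different classes
    raises :class:`InterclassError`.
    """
    for c in (class_a, class_b):
        if c not in (0, 1, 2):
            raise ValueError(f"class labels must be in {{0,1,2}}, got {c}")
    if class_a != class_b:
        raise InterclassError(
            f"interclass mixture ({class_a}, {class_b}) is out of scope"
        )
    return class_a


def split_then_pair(
    chemicals: Sequence,
    test_fraction: float,
    seed: int,
    n_test: int | None = None,
) -> tuple[list[MixturePair], list[MixturePair]]:
    """Partition chemicals, then enumerate pairs within each side only.

    The compound-disjoint construction: no chemical appears on both sides,
    and every cross-side pair is discarded, so
    ``|train| + |test| + n_train * n_test == C(n, 2)``. The test side gets
    ``ceil(n * test_fraction)`` chemicals unless that leaves a side with
    fewer than two; ``n_test`` overrides the rounding when a specific
    published partition size must be reproduced.
    """
    ids = _ids(chemicals)
    n = len(ids)
    if n < 4:
        raise InfeasibleSplitError("need at least 4 chemicals for a 2+2 split")
    if n_test is None:
        if not 0.0 < test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        n_test = math.ceil(n * test_fraction)
    n_test = max(2, min(n - 2, n_test))
    if n_test < 2 or n - n_test < 2:
        raise InfeasibleSplitError(f"split {n - n_test}/{n_test} leaves a side below 2")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ids_sorted = sorted(ids)
    test_ids = [ids_sorted[i] for i in perm[:n_test]]
    train_ids = [ids_sorted[i] for i in perm[n_test:]]
    return enumerate_pairs(train_ids), enumerate_pairs(test_ids)


def sample_pairs(pairs: Sequence[MixturePair], n: int, seed: int) -> list[MixturePair]:
    """Uniform sample of ``n`` pairs without replacement, canonical order kept."""
    if n > len(pairs):
        raise ValueError(f"cannot sample {n} pairs from {len(pairs)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=n, replace=False)
    idx.sort()
    return [pairs[i] for i in idx]


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two binary fingerprints.

    Fingerprints may be sets of on-bit indices or boolean/0-1 arrays.
    Defined as 0 when both fingerprints are empty.
    """
    if isinstance(fp_a, (set, frozenset)) or isinstance(fp_b, (set, frozenset)):
        a, b = set(fp_a), set(fp_b)
        union = len(a | b)
        return len(a & b) / union if union else 0.0
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    union = int(np.logical_or(a, b).sum())
    return int(np.logical_and(a, b).sum()) / union if union else 0.0


def morgan_fingerprints(records, radius: int = 2, n_bits: int = 1024) -> dict[str, set]:
    """Morgan (ECFP-like) on-bit sets for each record, keyed by chem_id."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = {}
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        fp = gen.GetFingerprint(mol)
        out[rec.chem_id] = set(fp.GetOnBits())
    return out


def tanimoto_stratified_sample(
    pairs: Sequence[MixturePair],
    fingerprints: Mapping[str, object],
    n_per_bin: int,
    bin_edges: tuple[float, float] = (0.3, 0.7),
    seed: int = 0,
) -> list[MixturePair]:
    """Representative sampling across low/medium/high structural similarity.

    Each pair is binned by the Tanimoto similarity of its two components at
    the given edges (low: sim < low edge, medium: in between, high:
    sim >= high edge); up to ``n_per_bin`` pairs are drawn uniformly per bin.
    """
    low, high = bin_edges
    if not 0.0 <= low < high <= 1.0:
        raise ValueError("bin edges must satisfy 0 <= low < high <= 1")
    bins: dict[str, list[MixturePair]] = {"low": [], "medium": [], "high": []}
    for pair in pairs:
        for cid in pair.key:
            if cid not in fingerprints:
                raise KeyError(f"no fingerprint for chemical {cid}")
        sim = tanimoto(fingerprints[pair.chem_a], fingerprints[pair.chem_b])
        if sim < low:
            bins["low"].append(pair)
        elif sim < high:
            bins["medium"].append(pair)
        else:
            bins["high"].append(pair)
    rng = np.random.default_rng(seed)
    out: list[MixturePair] = []
    for name in ("low", "medium", "high"):
        members = bins[name]
        k = min(n_per_bin, len(members))
        if k:
            idx = rng.choice(len(members), size=k, replace=False)
            idx.sort()
            out.extend(members[i] for i in idx)
    return out


def pairs_to_rows(pairs: Iterable[MixturePair], split: str | None = None) -> list[dict]:
    """Flatten pairs into dict rows for a mixtures CSV."""
    rows = []
    for p in pairs:
        row = {
            "chem_a": p.chem_a,
            "chem_b": p.chem_b,
            "x_a": p.x_a,
            "x_b": p.x_b,
            "binary_label": p.binary_label,
            "class_label": p.class_label,
            "td50_mix": p.td50_mix,
            "assumption_case": p.assumption_case,
        }
        if split is not None:
            row["split"] = split
        rows.append(row)
    return rows
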
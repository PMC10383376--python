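"""Mixture SMILES construction and ASCII tokenization.

A two-component mixture is written as the period-joined multi-component
SMILES ``s1 + "." + s2``. For neural-network input every SMILES character is
mapped through a fixed 94-symbol vocabulary — the printable ASCII characters,
decimal codes 33..126 — onto indices 1..94 (index = code - 32), with 0
reserved for padding. Vectors are post-padded with zeros or tail-truncated to
a uniform length L.
"""

from __future__ import annotations

import numpy as np

from .errors import EncodingError

#: Number of vocabulary symbols (printable ASCII, codes 33-126).
VOCAB_SIZE = 94
#: Padding token index.
PAD = 0
#: Default uniform vector length for mixture SMILES. Two drug-like SMILES
#: plus the separator rarely exceed this.
DEFAULT_LENGTH = 400


def build_vocab() -> dict[str, int]:
    """Character -> index mapping: '!' -> 1 ... '~' -> 94, ASCII order."""
    return {chr(c): c - 32 for c in range(33, 127)}


_VOCAB = build_vocab()
_INVERSE = {i: ch for ch, i in _VOCAB.items()}


def vocab_fingerprint() -> str:
    """Stable short identifier of the vocabulary, recorded in model manifests."""
    import hashlib

    payload = ";".join(f"{ch}:{i}" for ch, i in sorted(_VOCAB.items()))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def concat_mixture_smiles(s1: str, s2: str) -> str:
    """Join two component SMILES into one mixture SMILES with a '.' separator."""
    if not s1 or not s2:
        raise ValueError("component SMILES must be nonempty")
    return f"{s1}.{s2}"


def encode(s: str, length: int = DEFAULT_LENGTH, vocab: dict[str, int] | None = None) -> np.ndarray:
    """Encode a SMILES string as a fixed-length integer vector.

    The first ``min(len(s), length)`` entries are the per-character indices
    in order; the remainder is zero padding. Characters beyond ``length`` are
    dropped (tail truncation). Out-of-vocabulary characters (codes outside
    33..126, e.g. whitespace) raise :class:`EncodingError` naming the
    character and its position.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    vocab = _VOCAB if vocab is None else vocab
    out = np.zeros(length, dtype=np.int64)
    for pos, ch in enumerate(s[:length]):
        try:
            out[pos] = vocab[ch]
        except KeyError:
            raise EncodingError(
                f"character {ch!r} at position {pos} is outside the vocabulary"
            ) from None
    # validate the truncated tail too: an OOV character is an input error
    # regardless of where truncation would have cut it off
    for pos, ch in enumerate(s[length:], start=length):
        if ch not in vocab:
            raise EncodingError(
                f"character {ch!r} at position {pos} is outside the vocabulary"
            )
    return out


def decode(tokens, vocab: dict[str, int] | None = None) -> str:
    """Invert :func:`encode` for strings that fit the vector length.

    Zeros are only legal as a suffix; an interior zero marks a malformed
    encoding and raises :class:`EncodingError`.
    """
    inverse = _INVERSE if vocab is None else {i: ch for ch, i in vocab.items()}
    tokens = np.asarray(tokens)
    chars: list[str] = []
    seen_pad = False
    for pos, tok in enumerate(tokens):
        tok = int(tok)
        if tok == PAD:
            seen_pad = True
            continue
        if seen_pad:
            raise EncodingError(f"interior padding token before position {pos}")
        if tok not in inverse:
            raise EncodingError(f"token {tok} at position {pos} is out of range")
        chars.append(inverse[tok])
    return "".join(chars)


def encode_batch(smiles: list[str], length: int = DEFAULT_LENGTH) -> np.ndarray:
    """Encode a list of SMILES into an (n, length) token matrix."""
    if not smiles:
        return np.zeros((0, length), dtype=np.int64)
    return np.stack([encode(s, length) for s in smiles])
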
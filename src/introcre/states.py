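"""The 15-state chromatin alphabet (Roadmap core model) and helpers.

Chromatin segmentations assign every genomic interval, in every cell type,
one of 15 hidden-Markov-model-derived states.  A small subset of those
states marks candidate cis-regulatory elements (CREs): active transcription
start sites, their flanks, and enhancers.
"""

from __future__ import annotations

# Canonical mnemonics, in the conventional display order.
CHROMATIN_STATES: tuple[str, ...] = (
    "TssA",
    "TssAFlnk",
    "TxFlnk",
    "Tx",
    "TxWk",
    "EnhG",
    "Enh",
    "ZNF/Rpts",
    "Het",
    "TssBiv",
    "BivFlnk",
    "EnhBiv",
    "ReprPC",
    "ReprPCWk",
    "Quies",
)

#: States treated as cis-regulatory elements.
CRE_STATES: frozenset[str] = frozenset({"TssA", "TssAFlnk", "TxFlnk", "Enh", "EnhG"})

#: Sentinel for a position falling in no segment of a cell type's map.
UNANNOTATED = "UNANNOTATED"

# Mnemonic aliases seen in the wild (filesystem-safe spellings, numeric
# prefixes as used in released segmentation files).
_ALIASES = {
    "ZNF_Rpts": "ZNF/Rpts",
    "ZNF-Rpts": "ZNF/Rpts",
    "ZNF/Rpts": "ZNF/Rpts",
}
for _i, _s in enumerate(CHROMATIN_STATES, start=1):
    _ALIASES[_s] = _s
    _ALIASES[f"{_i}_{_s.replace('/', '_')}"] = _s


def normalize_state(label: str) -> str:
    """Map a state label (possibly an alias like ``ZNF_Rpts`` or
    ``8_ZNF_Rpts``) to its canonical mnemonic.

    Raises ``ValueError`` for labels outside the 15-state alphabet.
    """
    try:
        return _ALIASES[label.strip()]
    except KeyError:
        raise ValueError(
            f"unknown chromatin state {label!r}; expected one of {sorted(CHROMATIN_STATES)}"
        ) from None
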
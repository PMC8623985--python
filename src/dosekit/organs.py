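"""Controlled organ vocabulary for biodistribution tables.

Gamma-counting studies report a conventional organ panel; the default
vocabulary below is the panel of a mouse biodistribution with an implanted
tumor (blood and urine included as pseudo-organs). Matching is
case-insensitive and an alias map absorbs the common table abbreviations
("Small int.", "BM", ...). The vocabulary is extensible at load time.
"""

from __future__ import annotations

# Default organ panel (order is the conventional table order).
DEFAULT_ORGANS: tuple[str, ...] = (
    "blood",
    "heart",
    "lung",
    "liver",
    "stomach",
    "small intestine",
    "large intestine",
    "spleen",
    "pancreas",
    "kidney",
    "bone",
    "muscle",
    "tumor",
    "bone marrow",
    "brain",
    "urine",
)

# Common table abbreviations -> canonical name (keys lower-case).
ALIASES: dict[str, str] = {
    "small int.": "small intestine",
    "small int": "small intestine",
    "small intestine": "small intestine",
    "large int.": "large intestine",
    "large int": "large intestine",
    "bm": "bone marrow",
    "bone-marrow": "bone marrow",
    "kidneys": "kidney",
    "lungs": "lung",
}


def normalize_organ(name: str, extra_organs: tuple[str, ...] = ()) -> str | None:
    """Return the canonical organ name, or None if unknown.

    Parameters
    ----------
    name:
        Organ label as found in an input file (any case, may be an alias).
    extra_organs:
        Additional canonical names accepted besides :data:`DEFAULT_ORGANS`.
    """
    key = name.strip().lower()
    if key in ALIASES:
        key = ALIASES[key]
    vocab = set(DEFAULT_ORGANS) | {o.lower() for o in extra_organs}
    return key if key in vocab else None
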
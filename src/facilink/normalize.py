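"""Facility-name normalization.

Raw facility names as reported by sources mix casing, French diacritics,
facility-type prefixes ("PS Nemataba" vs "Nemataba Poste de Santé"),
contracted acronyms ("St." for "Saint") and roman numbering ("Dispensaire II").
Matching operates on a canonical *match name* produced by a fixed sequence of
lossy transformations:

1. transliterate accented Latin letters to ASCII and drop every remaining
   character outside ``[a-z0-9 ]``;
2. lowercase;
3. remove facility-type tokens at word boundaries (longest token first);
4. expand acronyms from the lexicon;
5. convert a standalone *terminal* roman-numeral token to arabic digits;
6. collapse whitespace runs and trim.

The transform is total and idempotent; an input that normalizes to the empty
string is returned as such and must be flagged by the caller rather than
dropped.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field

__all__ = ["NormalizationLexicon", "DEFAULT_LEXICON", "normalize_name", "strip_accents"]

# Facility-type vocabulary removed from names before matching.  Longer phrases
# are listed (and applied) before their abbreviations so "poste de sante" is
# consumed before a lone "ps" could be.
DEFAULT_TYPE_TOKENS: tuple[str, ...] = (
    "centre hospitalier universitaire",
    "centre hospitalier regional",
    "centre hospitalier national",
    "centre hospitalier",
    "centre de sante",
    "poste de sante",
    "case de sante",
    "health center",
    "health centre",
    "health post",
    "health hut",
    "dispensaire",
    "hopital",
    "hospital",
    "clinique",
    "cabinet",
    "cds",
    "chr",
    "chu",
    "eps",
    "ps",
    "cs",
    "hp",
)

# Connector words stranded at the start of a name once a leading type phrase is
# removed ("Hopital de Fatick" -> "de fatick" -> "fatick").
_LEADING_CONNECTORS = ("de", "du", "des", "d", "la", "le", "les", "l")

_ROMAN_VALUES = {
    "i": 1, "ii": 2, "iii": 3, "iv": 4, "v": 5, "vi": 6, "vii": 7,
    "viii": 8, "ix": 9, "x": 10, "xi": 11, "xii": 12, "xiii": 13,
    "xiv": 14, "xv": 15, "xvi": 16, "xvii": 17, "xviii": 18, "xix": 19,
    "xx": 20,
}


@dataclass(frozen=True)
class NormalizationLexicon:
    """Vocabulary driving name normalization.

    Parameters
    ----------
    type_tokens
        Facility-type strings removed from names; applied longest-first.
    acronym_map
        Word-boundary acronym expansions (keys compared accent-free,
        lowercase, without trailing dots).
    roman_numeral_limit
        Largest roman-numeral value converted to digits; terminal tokens
        above the limit are left untouched.
    """

    type_tokens: tuple[str, ...] = DEFAULT_TYPE_TOKENS
    acronym_map: dict[str, str] = field(
        default_factory=lambda: {"st": "saint", "ste": "sainte", "ndr": "notre dame"}
    )
    roman_numeral_limit: int = 20

    def sorted_type_tokens(self) -> list[str]:
        return sorted(self.type_tokens, key=len, reverse=True)


DEFAULT_LEXICON = NormalizationLexicon()


def strip_accents(text: str) -> str:
    """Transliterate accented Latin characters to their ASCII base letter."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def _remove_type_tokens(text: str, lexicon: NormalizationLexicon) -> str:
    for token in lexicon.sorted_type_tokens():
        # token boundaries: never delete "ps" inside "passy"
        text = re.sub(rf"\b{re.escape(token)}\b", " ", text)
    return text


def _strip_leading_connectors(tokens: list[str]) -> list[str]:
    while tokens and tokens[0] in _LEADING_CONNECTORS:
        tokens = tokens[1:]
    return tokens


def _expand_acronyms(tokens: list[str], lexicon: NormalizationLexicon) -> list[str]:
    out: list[str] = []
    for tok in tokens:
        expansion = lexicon.acronym_map.get(tok)
        out.extend(expansion.split() if expansion else [tok])
    return out


def _convert_terminal_roman(tokens: list[str], limit: int) -> list[str]:
    if not tokens:
        return tokens
    value = _ROMAN_VALUES.get(tokens[-1])
    # only a standalone terminal token is converted, so names containing
    # "vi"/"xi" mid-string are never corrupted
    if value is not None and value <= limit and len(tokens) > 1:
        return tokens[:-1] + [str(value)]
    return tokens


def normalize_name(raw: str, lexicon: NormalizationLexicon = DEFAULT_LEXICON) -> str:
    """Produce the match-ready form of a raw facility name.

    >>> normalize_name("Case de Santé Ndiaye")
    'ndiaye'
    >>> normalize_name("Facility iii")
    'facility 3'
    """
    text = strip_accents(raw).lower()
    text = re.sub(r"[^a-z0-9 ]", " ", text)
    text = _remove_type_tokens(text, lexicon)
    tokens = text.split()
    tokens = _strip_leading_connectors(tokens)
    tokens = _expand_acronyms(tokens, lexicon)
    tokens = _convert_terminal_roman(tokens, lexicon.roman_numeral_limit)
    return " ".join(tokens)
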
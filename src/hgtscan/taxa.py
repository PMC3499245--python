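"""Closed taxon vocabulary for database partitions.

Searches are run against six taxon-specific database partitions: Metazoa plus
five potential donor lineages.  Labels are normalised to one canonical
spelling; common variants (e.g. "Archea", "Other Eukaryotes") are accepted on
input.
"""

from __future__ import annotations

METAZOA = "Metazoa"
EUBACTERIA = "Eubacteria"
ARCHAEA = "Archaea"
FUNGI = "Fungi"
PLANTAE = "Plantae"
OTHER_EUKARYOTES = "OtherEukaryotes"

#: Non-metazoan partitions, in the fixed order used for tie-breaking.
FOREIGN_TAXA: tuple[str, ...] = (EUBACTERIA, ARCHAEA, FUNGI, PLANTAE, OTHER_EUKARYOTES)

#: All partitions.
TAXA: tuple[str, ...] = (METAZOA,) + FOREIGN_TAXA

_ALIASES = {
    "metazoa": METAZOA,
    "eubacteria": EUBACTERIA,
    "bacteria": EUBACTERIA,
    "archaea": ARCHAEA,
    "archea": ARCHAEA,  # spelling variant seen in the wild
    "fungi": FUNGI,
    "plantae": PLANTAE,
    "plants": PLANTAE,
    "viridiplantae": PLANTAE,
    "othereukaryotes": OTHER_EUKARYOTES,
    "other eukaryotes": OTHER_EUKARYOTES,
    "other_eukaryotes": OTHER_EUKARYOTES,
    "other-eukaryotes": OTHER_EUKARYOTES,
}


class TaxonError(ValueError):
    """A label outside the closed six-taxon vocabulary."""


def normalize_taxon(label: str) -> str:
    """Map a taxon label to its canonical form.

    Raises :class:`TaxonError` for labels outside the vocabulary.
    """
    try:
        return _ALIASES[str(label).strip().lower()]
    except KeyError:
        raise TaxonError(
            f"unknown taxon label {label!r}; expected one of {', '.join(TAXA)}"
        ) from None
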
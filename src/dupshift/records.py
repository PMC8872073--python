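"""Core record types and package exceptions."""

from __future__ import annotations

from dataclasses import dataclass, field

from ._codon import is_valid_cds, translate


class DupshiftError(Exception):
    """Base class for package errors."""


class InvalidConfigError(DupshiftError, ValueError):
    pass


class InvalidInputError(DupshiftError, ValueError):
    pass


class DegenerateAlignmentError(DupshiftError):
    """Best path aligns no CDS nucleotides at all."""


class UnresolvedPolarityError(DupshiftError):
    """Original/derived assignment cannot be decided for a pair."""


class ScenarioDegenerateError(DupshiftError):
    """A simulated frameshift scenario produced an unusable ORF; redraw."""


@dataclass
class GeneRecord:
    """A gene: its transcripts' CDSs plus species tag and genomic flanks.

    The first transcript is the canonical one.  Every CDS is expected to start
    with ATG, end with a stop codon and contain no internal in-frame stop.
    """

    gene_id: str
    species: str
    transcripts: list[str] = field(default_factory=list)
    flank5: str = ""
    flank3: str = ""
    role: str = ""  # original / derived / outgroup / "" for real data

    @property
    def cds(self) -> str:
        """Canonical (first) transcript CDS."""
        if not self.transcripts:
            raise InvalidInputError(f"gene {self.gene_id} has no transcripts")
        return self.transcripts[0]

    @property
    def protein(self) -> str:
        """Canonical protein, stop codon stripped."""
        aa = translate(self.cds)
        return aa[:-1] if aa.endswith("*") else aa

    def is_valid(self) -> bool:
        return bool(self.transcripts) and all(is_valid_cds(t) for t in self.transcripts)
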
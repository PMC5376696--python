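"""Phage-assay arithmetic: particle titer from UV absorbance.

Filamentous phage concentration is estimated spectrophotometrically: the
absorbance at 269 nm tracks the nucleotide content of the packaged
single-stranded genome, and the reading at 320 nm (where neither DNA nor
protein absorbs) corrects for light scattering. The classic conversion is

    particles/mL = (A269 - A320) * 6e16 / genome_length_nt

with the constant 6e16 from the standard spectrophotometric phage
quantification method (Day & Wiseman's formula as popularised in phage
display protocols). The genome length is an explicit input because phagemid
particles package vector-dependent genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidReadingError

#: Particles per mL per corrected absorbance unit per nucleotide; the
#: constant of the standard A269/A320 phage titer formula.
PARTICLES_PER_AU_NT = 6e16


@dataclass(frozen=True)
class TiterReading:
    """One spectrophotometric reading of a phage preparation.

    a269 / a320: absorbance units at 269 nm and 320 nm.
    genome_length: packaged genome size in nucleotides.
    """

    a269: float
    a320: float
    genome_length: float

    def __post_init__(self) -> None:
        if self.a269 < 0 or self.a320 < 0:
            raise InvalidReadingError("absorbances must be >= 0")
        if self.a269 < self.a320:
            raise InvalidReadingError(
                "A269 < A320: scatter-corrected absorbance would be negative")
        if self.genome_length <= 0:
            raise InvalidReadingError("genome_length must be > 0")


def phage_titer(reading: TiterReading) -> float:
    """Phage particle concentration (particles per mL).

    Linear in the scatter-corrected absorbance A269 - A320 and inversely
    proportional to the genome length.
    """
    return (reading.a269 - reading.a320) * PARTICLES_PER_AU_NT / reading.genome_length
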
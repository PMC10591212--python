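"""In-silico tryptic digestion of collagen chains.

Trypsin cleaves C-terminal to K or R, classically suppressed when the next
residue is proline. Collagen peptides are named after the chain and the
1-based start position of the peptide within the mature chain (Brown-style
nomenclature, e.g. ``COL1a2 568``), which makes names positional and lets
homologous peptides in different species share a name.
"""

from __future__ import annotations

from dataclasses import dataclass

from zoomskit.collagen_seq import CollagenChain, mature_sequence


@dataclass(frozen=True)
class DigestParams:
    """Tryptic digestion parameters.

    Defaults (2 missed cleavages, length 6-60) span the peptide sizes that are
    informative in ZooMS MALDI fingerprints. ``cleave_before_proline`` relaxes
    the classical K/R-not-before-P rule; some empirically observed collagen
    peptides begin with proline, implying such a cleavage.
    """

    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 60
    cleave_before_proline: bool = False

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if not (1 <= self.min_length <= self.max_length):
            raise ValueError("need 1 <= min_length <= max_length")


@dataclass(frozen=True)
class Peptide:
    """A located tryptic peptide of one species' collagen chain.

    ``start`` is 1-based within the mature chain. ``missed_cleavages`` counts
    internal cleavage sites retained in the peptide.
    """

    species_id: str
    chain_id: str
    start: int
    sequence: str
    missed_cleavages: int

    @property
    def end(self) -> int:
        """1-based inclusive end position in the mature chain."""
        return self.start + len(self.sequence) - 1

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


def cleavage_sites(sequence: str, cleave_before_proline: bool = False) -> list[int]:
    """0-based indices *after* which trypsin cleaves ``sequence``."""
    n = len(sequence)
    return [
        i
        for i in range(n - 1)
        if sequence[i] in "KR"
        and (cleave_before_proline or sequence[i + 1] != "P")
    ]


def tryptic_peptides(
    chain: CollagenChain, params: DigestParams = DigestParams()
) -> list[Peptide]:
    """Digest the mature region of ``chain`` into located peptides.

    Returns every peptide obtainable by cleaving after K/R (suppressed before
    P unless ``params.cleave_before_proline``) and joining up to
    ``max_missed_cleavages`` adjacent fragments, filtered to the length
    bounds; sorted by start then length. Deterministic.
    """
    seq = mature_sequence(chain)
    if not seq:
        return []
    cuts = cleavage_sites(seq, params.cleave_before_proline)
    # fragment boundaries as half-open [b, e) 0-based slices
    bounds = [0] + [c + 1 for c in cuts] + [len(seq)]
    frags = list(zip(bounds[:-1], bounds[1:]))
    out: list[Peptide] = []
    for i in range(len(frags)):
        for k in range(params.max_missed_cleavages + 1):
            j = i + k
            if j >= len(frags):
                break
            b, e = frags[i][0], frags[j][1]
            if not (params.min_length <= e - b <= params.max_length):
                continue
            out.append(
                Peptide(
                    species_id=chain.species_id,
                    chain_id=chain.chain_id,
                    start=b + 1,
                    sequence=seq[b:e],
                    missed_cleavages=k,
                )
            )
    out.sort(key=lambda p: (p.start, len(p.sequence)))
    return out


def peptide_name(p: Peptide) -> str:
    """Positional Brown-style name: chain label + space + mature start."""
    return f"{p.chain_id} {p.start}"
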
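"""Codon selection tables for deterministic reverse translation.

``HUMAN_HIGH_FREQUENCY_CODONS`` maps each amino acid to the codon most used
in human coding sequences (Kazusa codon-usage census of the human
transcriptome), plus ``*`` for the stop. A deterministic one-codon-per-residue
policy keeps CDS emission reproducible; it is a design policy, not an
expression-optimization claim.
"""

HUMAN_HIGH_FREQUENCY_CODONS: dict[str, str] = {
    "A": "GCC",
    "C": "TGC",
    "D": "GAC",
    "E": "GAG",
    "F": "TTC",
    "G": "GGC",
    "H": "CAC",
    "I": "ATC",
    "K": "AAG",
    "L": "CTG",
    "M": "ATG",
    "N": "AAC",
    "P": "CCC",
    "Q": "CAG",
    "R": "AGA",
    "S": "AGC",
    "T": "ACC",
    "V": "GTG",
    "W": "TGG",
    "Y": "TAC",
    "*": "TGA",
}
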
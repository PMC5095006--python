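"""Small nucleotide-string helpers shared across modules."""

_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (U treated as T)."""
    return seq.translate(_COMP)[::-1]


def normalize(seq: str) -> str:
    """Uppercase DNA alphabet; RNA U mapped to T."""
    return seq.upper().replace("U", "T")
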
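"""FASTA/TSV helpers shared across modules."""

from __future__ import annotations

import io

from Bio import SeqIO


def write_fasta(sequences: dict[str, str], width: int = 60) -> str:
    """Render a name->sequence mapping as FASTA text wrapped at ``width``."""
    chunks = []
    for name, seq in sequences.items():
        chunks.append(f">{name}")
        for k in range(0, len(seq), width):
            chunks.append(seq[k:k + width])
    return "\n".join(chunks) + "\n"


def read_fasta(text_or_path) -> dict[str, str]:
    """Parse FASTA text or a path into an ordered name->sequence dict."""
    try:
        is_path = "\n" not in text_or_path and not text_or_path.startswith(">")
    except TypeError:
        is_path = True
    handle = open(text_or_path) if is_path else io.StringIO(text_or_path)
    with handle:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}
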
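"""Reading and writing pipe-delimited segmentation files.

One sequence per line, unit forms joined by ``|`` with the final token's
trailing space stripped, e.g. ``i was |trying to |make |up |my mind |what
|to do``.  Files produced by external segmenters (e.g. Adaptor Grammar
output converted to this layout) can be scored by reading them back against
the corpus they segment.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence as TSequence

from .core import Corpus, SegmentationResult, UnitToken


def write_segmentations(
    results: TSequence[SegmentationResult], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in results:
            fh.write("|".join(t.form for t in r.tokens).rstrip(" ") + "\n")


def read_segmentations(path: str | Path, corpus: Corpus) -> list[SegmentationResult]:
    """Parse a segmentation file against the corpus it covers.

    Each line must concatenate (with the final trailing space restored) to
    the rendered form of the corresponding sequence.
    """
    results: list[SegmentationResult] = []
    with Path(path).open(encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) != len(corpus.sequences):
        raise ValueError(
            f"{path}: {len(lines)} segmentations for {len(corpus.sequences)} sequences"
        )
    for lineno, (line, seq) in enumerate(zip(lines, corpus), start=1):
        parts = line.split("|")
        rendered = seq.rendered
        if not parts[-1].endswith(" "):
            parts[-1] += " "
        tokens: list[UnitToken] = []
        pos = 0
        for part in parts:
            if not rendered.startswith(part, pos):
                raise ValueError(
                    f"{path}:{lineno}: unit {part!r} does not match the "
                    f"sequence at offset {pos}"
                )
            tokens.append(UnitToken(part, (pos, pos + len(part))))
            pos += len(part)
        if pos != len(rendered):
            raise ValueError(
                f"{path}:{lineno}: segmentation covers {pos} of "
                f"{len(rendered)} characters"
            )
        results.append(SegmentationResult(tokens=tokens))
    return results
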
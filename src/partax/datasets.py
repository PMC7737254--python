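"""Published per-size audit count tables used as worked examples.

Two hierarchy-scale audit studies of concepts sampled from partial-area
taxonomies, reported at the level of per-partial-area-size sampled and
erroneous concept counts:

- ``SPECIMEN``: the SNOMED CT *Specimen* hierarchy (January 2018
  release; 1696 concepts, 23 areas, 530 partial-areas; 100 concepts
  sampled from the 1463 non-overlapping ones, 50 from small partial-areas
  sizes 1–10 allocated proportionally and 50 from large ones).
- ``GENE``: the NCIt *Gene* hierarchy (March 2018 release; 10,117
  concepts, 143 areas, 5594 partial-areas; 100 concepts sampled from the
  10,005 non-overlapping ones, 10 at size 1 and 5 per size 2–10 plus 50
  large — the size-9 stratum is empty).

Each table maps partial-area size (or ``'gt'`` for sizes above the
initial bound 10) to ``(population, sampled, erroneous)`` counts, where
``population`` is the number of non-overlapping concepts of that size in
the full hierarchy.
"""

from __future__ import annotations

from .audit import SizeErrorTable

__all__ = [
    "SPECIMEN_COUNTS",
    "GENE_COUNTS",
    "specimen_size_error_table",
    "gene_size_error_table",
]

# size -> (eligible population, sampled, erroneous)
SPECIMEN_COUNTS = {
    1: (345, 22, 3),
    2: (120, 8, 1),
    3: (61, 4, 2),
    4: (40, 3, 1),
    5: (39, 2, 1),
    6: (51, 3, 0),
    7: (36, 2, 1),
    8: (28, 2, 0),
    9: (52, 3, 2),
    10: (10, 1, 0),
    "gt": (681, 50, 3),
}

GENE_COUNTS = {
    1: (5450, 10, 9),
    2: (180, 5, 4),
    3: (12, 5, 1),
    4: (20, 5, 3),
    5: (10, 5, 3),
    6: (6, 5, 3),
    7: (14, 5, 2),
    8: (16, 5, 1),
    10: (9, 5, 3),
    "gt": (4288, 50, 33),
}

_BOUND = 10


def specimen_size_error_table() -> SizeErrorTable:
    """Specimen-hierarchy audit outcome as a :class:`SizeErrorTable`."""
    return SizeErrorTable.from_counts(
        {k: (s, e) for k, (_, s, e) in SPECIMEN_COUNTS.items()}, bound=_BOUND
    )


def gene_size_error_table() -> SizeErrorTable:
    """Gene-hierarchy audit outcome as a :class:`SizeErrorTable`."""
    return SizeErrorTable.from_counts(
        {k: (s, e) for k, (_, s, e) in GENE_COUNTS.items()}, bound=_BOUND
    )
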
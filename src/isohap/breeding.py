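"""Backcross genome-homogenisation arithmetic for introgression line designs.

An Iso-Y style line repeatedly backcrosses males carrying a focal (Y-linked)
phenotype into a randomly mating stock population. Each backcross generation
halves the expected fraction of the founder's autosomal genome that remains
linked to nothing, so after g generations only (1/2)^g of the background is
expected to derive from the founder; everything except the selected region is
homogenised with the stock.
"""

from __future__ import annotations


def homogenised_fraction(generations: int) -> float:
    """Expected fraction of the genome homogenised after ``generations``
    backcrosses: 1 - (1/2)^g."""
    if generations < 0:
        raise ValueError("generations must be >= 0")
    return 1.0 - 0.5 ** generations


def residual_parental_fraction(generations: int) -> float:
    """Expected residual founder-genome fraction after ``generations``
    backcrosses: (1/2)^g."""
    if generations < 0:
        raise ValueError("generations must be >= 0")
    return 0.5 ** generations
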
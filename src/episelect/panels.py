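"""Built-in HLA allele panels.

The default panels are the IEDB reference sets of 27 class-I alleles
(HLA-A and HLA-B) and 27 class-II alleles (DRB1/3/4/5 plus paired
alpha/beta DP and DQ units) commonly used for population-level epitope
binding surveys.  Both can be overridden from configuration.
"""

from __future__ import annotations

from .core import HlaAllele, allele_from_name

_CLASS_I_NAMES = (
    "HLA-A*01:01", "HLA-A*02:01", "HLA-A*02:03", "HLA-A*02:06",
    "HLA-A*03:01", "HLA-A*11:01", "HLA-A*23:01", "HLA-A*24:02",
    "HLA-A*26:01", "HLA-A*30:01", "HLA-A*30:02", "HLA-A*31:01",
    "HLA-A*32:01", "HLA-A*33:01", "HLA-A*68:01", "HLA-A*68:02",
    "HLA-B*07:02", "HLA-B*08:01", "HLA-B*15:01", "HLA-B*35:01",
    "HLA-B*40:01", "HLA-B*44:02", "HLA-B*44:03", "HLA-B*51:01",
    "HLA-B*53:01", "HLA-B*57:01", "HLA-B*58:01",
)

_CLASS_II_NAMES = (
    "HLA-DRB1*01:01", "HLA-DRB1*03:01", "HLA-DRB1*04:01", "HLA-DRB1*04:05",
    "HLA-DRB1*07:01", "HLA-DRB1*08:02", "HLA-DRB1*09:01", "HLA-DRB1*11:01",
    "HLA-DRB1*12:01", "HLA-DRB1*13:02", "HLA-DRB1*15:01",
    "HLA-DRB3*01:01", "HLA-DRB3*02:02", "HLA-DRB4*01:01", "HLA-DRB5*01:01",
    "HLA-DPA1*01:03/DPB1*02:01", "HLA-DPA1*01:03/DPB1*04:01",
    "HLA-DPA1*02:01/DPB1*01:01", "HLA-DPA1*02:01/DPB1*05:01",
    "HLA-DPA1*02:01/DPB1*14:01", "HLA-DPA1*03:01/DPB1*04:02",
    "HLA-DQA1*01:01/DQB1*05:01", "HLA-DQA1*01:02/DQB1*06:02",
    "HLA-DQA1*03:01/DQB1*03:02", "HLA-DQA1*04:01/DQB1*04:02",
    "HLA-DQA1*05:01/DQB1*02:01", "HLA-DQA1*05:01/DQB1*03:01",
)


def class_i_panel() -> list[HlaAllele]:
    """The 27 built-in MHC class-I alleles (HLA-A, HLA-B)."""
    return [allele_from_name(n) for n in _CLASS_I_NAMES]


def class_ii_panel() -> list[HlaAllele]:
    """The 27 built-in MHC class-II alleles (DR, DP, DQ)."""
    return [allele_from_name(n) for n in _CLASS_II_NAMES]


def panel_from_names(names) -> list[HlaAllele]:
    return [allele_from_name(n) for n in names]
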
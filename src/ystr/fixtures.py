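"""Packaged study data: the three printed haplotype tables and the named
founder signatures.

The haplotype tables ship as package-data CSV in the standard dialect and are
loaded through the public reader, so the files are the single source of
truth.  Populations: ``obrien`` (10 surname-linked males), ``irish`` (10
general Irish males), ``control`` (22 randomly sampled males).

Signatures: ``dal_riata`` — the six-locus haplotype of the Dal Riata, an
early-medieval Gaelic overkingdom (note its printed DYS389II value of 16 is
kept exactly as published even though it lies outside the table range at
that locus; shipped classifications ignore DYS389II, so it never bites);
``obrien_footprint`` — the 14-locus modal footprint of the O'Brien surname
project; ``sykes`` — the four-microsatellite footprint of the Sykes surname
study.
"""

from __future__ import annotations

from importlib import resources

from .core import AlleleSet, FounderSignature, Population
from .io import read_population

__all__ = ["get_fixture_population", "get_fixture_signature",
           "FIXTURE_POPULATIONS", "FIXTURE_SIGNATURES"]

FIXTURE_POPULATIONS = ("obrien", "irish", "control")

_SIGNATURE_DEFS: dict[str, dict[str, tuple[int, ...]]] = {
    "dal_riata": {
        "DYS393": (13,), "DYS390": (25,), "DYS19": (14,),
        "DYS391": (11,), "DYS389I": (13,), "DYS389II": (16,),
    },
    "obrien_footprint": {
        "DYS389I": (13,), "DYS390": (24,), "DYS389II": (29,), "DYS458": (17,),
        "DYS19": (14,), "DYS385": (11, 14), "DYS393": (13,), "DYS391": (11,),
        "DYS439": (11,), "DYS392": (13,), "YGATAH4": (11,), "DYS437": (15,),
        "DYS438": (12,), "DYS448": (19,),
    },
    "sykes": {
        "DYS19": (15,), "DYS390": (23,), "DYS391": (11,), "DYS393": (14,),
    },
}

FIXTURE_SIGNATURES = tuple(_SIGNATURE_DEFS)


def get_fixture_population(name: str) -> Population:
    """Load one of the packaged study populations by name.

    ``name`` is one of ``obrien``, ``irish``, ``control``.
    """
    if name not in FIXTURE_POPULATIONS:
        raise KeyError(
            f"unknown fixture population {name!r}; "
            f"valid names: {', '.join(FIXTURE_POPULATIONS)}"
        )
    text = resources.files("ystr.data").joinpath(f"{name}.csv").read_text("utf-8")
    return read_population(text, name=name)


def get_fixture_signature(name: str) -> FounderSignature:
    """Load one of the named founder signatures.

    ``name`` is one of ``dal_riata``, ``obrien_footprint``, ``sykes``.
    """
    if name not in _SIGNATURE_DEFS:
        raise KeyError(
            f"unknown fixture signature {name!r}; "
            f"valid names: {', '.join(_SIGNATURE_DEFS)}"
        )
    return FounderSignature(
        name=name,
        locus_values={
            locus: AlleleSet(alleles)
            for locus, alleles in _SIGNATURE_DEFS[name].items()
        },
    )
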
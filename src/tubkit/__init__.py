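"""tubkit: resolving a multi-isotype gene family in an allopolyploid genome.

Mining by local alignment, ancestral-block reconstruction, homeolog /
paralog / pseudogene classification, NG86 Ka/Ks, NJ isotype clading and
per-subgenome expression contributions — plus a synthetic allohexaploid
generator with full ground truth for end-to-end testing.
"""

from importlib.resources import files as _files

__version__ = "0.1.0"


def inventory_path(family: str):
    """Path to a packaged reference-inventory TSV (``tua``/``tub``/``tug``)."""
    name = family.lower()
    if name not in ("tua", "tub", "tug"):
        raise ValueError("family must be one of tua, tub, tug")
    return _files("tubkit").joinpath(f"data/inventory/{name}.tsv")


def motif_path(family: str):
    """Path to a packaged motif-model JSON fixture (``tua``/``tub``/``tug``)."""
    name = family.lower()
    if name not in ("tua", "tub", "tug"):
        raise ValueError("family must be one of tua, tub, tug")
    return _files("tubkit").joinpath(f"data/motifs/{name}_motifs.json")
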
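"""linrep: structural analysis of linear bacterial replicons.

A toolkit for the computational side of finishing and comparing linear
chromosomes and giant linear plasmids (GLPs) of high-GC actinomycetes:

* virtual rare-cutter digestion with pulsed-field gel (PFGE) band matching,
  for assembly validation against an observed gel;
* detection of assembler-collapsed long terminal inverted repeats from read
  depth, with full-length (2R + C) reconstruction;
* anchor-based comparison of near-identical plasmids into synteny blocks,
  rearrangement events and SNP calls with coding-effect classification;
* transposase density and breakpoint-proximity enrichment statistics;
* a seeded synthetic-data generator providing ground truth for all of it.
"""

__version__ = "0.1.0"

from . import io  # noqa: F401  (submodules re-exported lazily below)

__all__ = ["io", "digest", "repeats", "compare", "mobile", "simulate", "__version__"]


def __getattr__(name):
    if name in __all__:
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
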
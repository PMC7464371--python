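"""Bundled example data.

The package ships the study-design table of the adipose-derived stem cell
meta-analysis (45 samples over 11 GEO series) transcribed as a manifest TSV,
so the sample accounting of that study can be reproduced without network
access.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io_manifest import SampleManifest, parse_manifest


def adsc_manifest_path() -> Path:
    """Path of the bundled hADSC study manifest TSV."""
    return Path(resources.files("txmap") / "data" / "adsc_manifest.tsv")


def load_adsc_manifest() -> SampleManifest:
    """The hADSC study design: 12 male (pool A) and 33 female (pool B)
    samples, the females split 9 (C, FGF medium) / 24 (D, standard medium)."""
    return parse_manifest(adsc_manifest_path())
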
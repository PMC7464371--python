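import logging

import numpy as np
import pandas as pd
import pytest

from txmap.io_manifest import (
    GeneLocus,
    GeneLocusMap,
    PlatformAnnotation,
    ProbeMatrix,
)

logging.getLogger("txmap").setLevel(logging.ERROR)


@pytest.fixture
def tiny_loci() -> GeneLocusMap:
    """Five genes on two chromosomes with hand-placed coordinates."""
    loci = {
        "AAA": GeneLocus("chr1", 100_000, 150_000),
        "BBB": GeneLocus("chr1", 300_000, 340_000),
        "CCC": GeneLocus("chr1", 600_000, 650_000),
        "DDD": GeneLocus("chr2", 50_000, 90_000),
        "EEE": GeneLocus("chr2", 260_000, 300_000),
    }
    return GeneLocusMap(loci, {"chr1": 1_000_000, "chr2": 500_000})


def make_matrix(values: dict[str, list], probes: list[str],
                scales: dict[str, str] | None = None,
                dataset_id: str = "DS", platform_id: str = "P") -> ProbeMatrix:
    data = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                        dtype=float)
    scales = scales or {s: "linear" for s in data.columns}
    return ProbeMatrix(dataset_id, platform_id, data, scales)


def write_tsv(path, text: str) -> str:
    path.write_text(text)
    return str(path)
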
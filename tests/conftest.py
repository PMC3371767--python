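import numpy as np
import pytest

from strandnorm.io_bed import Region
from strandnorm.synthetic import generate_synthetic_dataset, paper_preset


@pytest.fixture
def preset_dataset():
    """One seeded instance of the default demonstration scenario."""
    return generate_synthetic_dataset(paper_preset(seed=11))


@pytest.fixture
def preset_region(preset_dataset):
    cfg = preset_dataset.config
    return Region(cfg.chrom, 0, cfg.region_length)


@pytest.fixture
def write_bed(tmp_path):
    """Write BED6 lines from (chrom, start, end, strand) tuples; returns path."""

    def _write(records, name="reads.bed"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for i, (chrom, start, end, strand) in enumerate(records):
                fh.write(f"{chrom}\t{start}\t{end}\tr{i}\t0\t{strand}\n")
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
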
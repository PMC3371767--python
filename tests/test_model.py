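"""Genome-scale orchestration: sectioning, the model/results API, BED out."""

import numpy as np
import pandas as pd
import pytest

from strandnorm.io_bed import Region, extract_start_counts, read_aligned_reads
from strandnorm.model import (
    NormalizationConfig,
    StrandNormalizationModel,
    normalize_genome,
    partition_sections,
)
from strandnorm.synthetic import generate_synthetic_dataset, paper_preset


class TestPartitionSections:
    def test_three_sections_with_pads(self):
        sections = partition_sections(250_000, 100_000, 5)
        assert sections == [
            (0, 100_000, 0, 100_005),
            (100_000, 200_000, 99_995, 200_005),
            (200_000, 250_000, 199_995, 250_000),
        ]

    def test_short_chromosome_is_one_section(self):
        # pads are clipped at the chromosome ends
        assert partition_sections(50, 100_000, 5) == [(0, 50, 0, 50)]

    def test_cores_tile_without_overlap(self):
        sections = partition_sections(123_456, 30_000, 7)
        starts = [s[0] for s in sections]
        ends = [s[1] for s in sections]
        assert starts[0] == 0 and ends[-1] == 123_456
        assert starts[1:] == ends[:-1]
        # every coordinate belongs to exactly one core
        for coord in (0, 29_999, 30_000, 123_455):
            owners = [s for s in sections if s[0] <= coord < s[1]]
            assert len(owners) == 1


class TestNormalizationConfig:
    def test_rejects_section_shorter_than_one_window_step(self):
        with pytest.raises(ValueError, match="section_length"):
            NormalizationConfig(section_length=10, half_width=5, step=5)

    @pytest.mark.parametrize(
        "kwargs", [{"residual_threshold": 0.0}, {"fill_mode": "spline"},
                   {"read_length": 0}],
    )
    def test_rejects_invalid_values(self, kwargs):
        with pytest.raises(ValueError):
            NormalizationConfig(**kwargs)


class TestStrandNormalizationModel:
    def test_missing_control_chromosome_is_named(self, write_bed, tmp_path):
        chip = write_bed([("chr1", 10, 40, "+"), ("chr2", 10, 40, "+")], "chip.bed")
        ctrl = write_bed([("chr1", 10, 40, "+")], "ctrl.bed")
        with pytest.raises(ValueError, match="chr2"):
            StrandNormalizationModel.from_bed(chip, [ctrl])

    def test_read_length_auto_is_modal_chip_length(self, write_bed):
        chip = write_bed(
            [("chr1", 0, 36, "+"), ("chr1", 5, 41, "+"), ("chr1", 9, 39, "-")],
            "chip.bed",
        )
        ctrl = write_bed([("chr1", 0, 30, "+"), ("chr1", 3, 33, "-")], "c.bed")
        model = StrandNormalizationModel.from_bed(chip, [ctrl])
        assert model.resolved_read_length == 36

    def test_chip_identical_to_control_yields_no_output(self, tmp_path, write_bed):
        records = [("chr1", i * 37 % 900, i * 37 % 900 + 30, "+-"[i % 2])
                   for i in range(60)]
        chip = write_bed(records, "chip.bed")
        out = tmp_path / "out.bed"
        summary = normalize_genome(chip, [chip], out_path=out)
        assert summary.reads_out == 0
        assert out.read_text() == ""

    def test_empty_chip_file_yields_empty_output(self, tmp_path, write_bed):
        chip = tmp_path / "empty.bed"
        chip.write_text("")
        ctrl = write_bed([("chr1", 0, 30, "+")], "ctrl.bed")
        out = tmp_path / "out.bed"
        summary = normalize_genome(chip, [ctrl], out_path=out)
        assert summary.reads_in == 0
        assert summary.reads_out == 0
        assert out.read_text() == ""

    def test_deterministic_byte_identical_output(self, tmp_path):
        dataset = generate_synthetic_dataset(paper_preset(seed=5))
        paths = dataset.write_bed(tmp_path / "sim")
        outs = []
        for tag in ("a", "b"):
            out = tmp_path / f"out_{tag}.bed"
            normalize_genome(
                paths["chip"], [paths["control"]], out_path=out,
                chrom_sizes={"chrS": 2000},
            )
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]

    def test_end_to_end_output_confined_to_unique_peak(self, tmp_path):
        dataset = generate_synthetic_dataset(paper_preset(seed=2))
        paths = dataset.write_bed(tmp_path / "sim")
        out = tmp_path / "out.bed"
        normalize_genome(
            paths["chip"], [paths["control"]], out_path=out,
            chrom_sizes={"chrS": 2000},
        )
        reads = read_aligned_reads(out)
        assert reads, "expected some normalized signal"
        truth = {label: (s, e) for _, s, e, label in dataset.truth}
        lo, hi = truth["unique"]
        margin = 10  # smoothing support around the peak interval
        for read in reads:
            assert lo - margin <= read.start_position < hi + margin

    def test_coefficients_table_written_beside_output(self, tmp_path):
        dataset = generate_synthetic_dataset(paper_preset(seed=4))
        paths = dataset.write_bed(tmp_path / "sim")
        out = tmp_path / "out.bed"
        summary = normalize_genome(
            paths["chip"], [paths["control"]], out_path=out,
            chrom_sizes={"chrS": 2000},
        )
        table = pd.read_csv(f"{out}.coefficients.tsv", sep="\t")
        assert list(table["strand"]) == ["+", "-"]
        assert summary.sections_processed == 2
        assert (table["n_centres"] > 0).all()

    def test_results_summary_reports_fit(self, tmp_path):
        dataset = generate_synthetic_dataset(paper_preset(seed=6))
        paths = dataset.write_bed(tmp_path / "sim")
        model = StrandNormalizationModel.from_bed(
            paths["chip"], [paths["control"]], chrom_sizes={"chrS": 2000}
        )
        results = model.fit()
        results.to_bed(tmp_path / "o.bed")
        text = results.summary()
        assert "Sections fitted:     2" in text
        assert "Dummy reads written" in text
        coef = results.sections.filter(like="coef_").to_numpy()
        assert np.isfinite(coef).all()

    def test_pool_strands_fits_once_per_section(self, tmp_path):
        dataset = generate_synthetic_dataset(paper_preset(seed=7))
        paths = dataset.write_bed(tmp_path / "sim")
        model = StrandNormalizationModel.from_bed(
            paths["chip"], [paths["control"]], chrom_sizes={"chrS": 2000},
            config=NormalizationConfig(pool_strands=True),
        )
        results = model.fit()
        assert list(results.sections["strand"]) == ["both"]

    def test_section_boundaries_do_not_move_the_signal(self, tmp_path):
        """Cutting the same data into smaller sections relocates no signal."""
        dataset = generate_synthetic_dataset(
            paper_preset(seed=9, region_length=6000)
        )
        paths = dataset.write_bed(tmp_path / "sim")
        tracks = {}
        for length in (6000, 2000):
            out = tmp_path / f"o{length}.bed"
            normalize_genome(
                paths["chip"], [paths["control"]], out_path=out,
                config=NormalizationConfig(section_length=length),
                chrom_sizes={"chrS": 6000},
            )
            track = extract_start_counts(
                read_aligned_reads(out), Region("chrS", 0, 6000)
            )
            tracks[length] = track.counts_sense + track.counts_antisense
        both_hot = (tracks[6000] > 0) | (tracks[2000] > 0)
        assert both_hot.any()
        # hot positions agree up to fit differences at section boundaries
        agreement = (tracks[6000][both_hot] > 0) == (tracks[2000][both_hot] > 0)
        assert agreement.mean() > 0.8
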
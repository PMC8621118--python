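"""Synthetic-generator contracts: determinism, structure, round-trips."""

import numpy as np
import pytest
from scipy import stats

from bbscore.rate_selection import accumulated_information_profile, amplitude_spectrum
from bbscore.simulate import (
    RecordingParseError,
    SimConfig,
    generate_recording,
    generate_task_dataset,
    read_recording_csv,
    write_recording_csv,
)


def _cfg(**kw):
    base = dict(task_ids=(1, 2), class_counts={s: 4 for s in range(5)}, seed=3)
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_recording_bit_identical(self):
        cfg = _cfg()
        rec1, ann1 = generate_recording(cfg, 0)
        rec2, ann2 = generate_recording(cfg, 0)
        np.testing.assert_array_equal(rec1.data, rec2.data)
        assert ann1 == ann2

    def test_subjects_differ(self):
        cfg = _cfg()
        rec0, _ = generate_recording(cfg, 0)
        rec1, _ = generate_recording(cfg, 1)
        assert rec0.data.shape != rec1.data.shape or not np.array_equal(
            rec0.data, rec1.data
        )

    def test_task_dataset_reproducible(self):
        cfg = _cfg()
        ds1 = generate_task_dataset(cfg, 1)
        ds2 = generate_task_dataset(cfg, 1)
        np.testing.assert_array_equal(ds1.samples, ds2.samples)
        np.testing.assert_array_equal(ds1.labels, ds2.labels)


class TestStructure:
    def test_recording_shape_and_annotations(self):
        cfg = _cfg()
        rec, anns = generate_recording(cfg, 0)
        assert rec.data.shape[1] == 72
        assert [a.task_id for a in anns] == [1, 2]
        for a in anns:
            a.validate_against(rec)

    def test_class_counts_exact(self):
        counts = {0: 5, 1: 5, 2: 5, 3: 5, 4: 5}
        ds = generate_task_dataset(_cfg(class_counts=counts), 1)
        assert len(ds) == 25
        assert ds.class_counts() == counts

    def test_worst_imbalance_reproduced(self):
        """Emulates the most imbalanced clinical task: 56 score-4 records."""
        counts = {0: 10, 1: 10, 2: 10, 3: 10, 4: 56}
        ds = generate_task_dataset(_cfg(class_counts=counts, n_subjects=20), 1)
        assert ds.class_counts()[4] == 56

    def test_equal_lengths_after_padding(self):
        ds = generate_task_dataset(_cfg(), 2)
        assert ds.samples.ndim == 3  # one shared time axis by construction

    def test_task_not_configured_rejected(self):
        with pytest.raises(ValueError, match="not in configured"):
            generate_task_dataset(_cfg(task_ids=(1,)), 7)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(task_ids=())
        with pytest.raises(ValueError):
            SimConfig(class_counts={7: 3})
        with pytest.raises(ValueError):
            SimConfig(separation=-1.0)


class TestSignalContent:
    def test_zero_separation_classes_indistinguishable(self):
        """At separation 0, per-channel means/variances differ only by
        sampling noise between any two scores (alpha=0.01 per channel)."""
        cfg = _cfg(
            separation=0.0,
            class_counts={0: 12, 4: 12},
            task_ids=(1,),
            seed=9,
        )
        ds = generate_task_dataset(cfg, 1)
        a = ds.samples[ds.labels == 0]
        b = ds.samples[ds.labels == 4]
        # compare per-channel energy summaries across the two groups
        fa = np.sqrt((a**2).mean(axis=1))
        fb = np.sqrt((b**2).mean(axis=1))
        rejections = sum(
            stats.ttest_ind(fa[:, c], fb[:, c]).pvalue < 0.01 for c in range(72)
        )
        assert rejections <= 0.05 * 72

    def test_no_tremor_means_no_high_frequency_content(self):
        cfg = _cfg(tremor_level=0.0, task_ids=(1,))
        ds = generate_task_dataset(cfg, 1)
        n_fft = 1024
        amps = amplitude_spectrum(np.moveaxis(ds.samples, 1, 2), n_fft)
        freqs = np.arange(1, n_fft // 2 + 1) * cfg.sampling_rate_hz / n_fft
        frac = amps[..., freqs > 15].sum() / amps.sum()
        assert frac < 0.01

    def test_spectral_realism(self, small_corpus):
        """Default settings concentrate >=90% of amplitude below 10 Hz."""
        prof = accumulated_information_profile(small_corpus)
        assert prof.accumulated_percent[9] >= 90.0

    def test_separability_monotone_in_separation(self):
        """A fixed linear probe's CV accuracy does not decrease (on average
        over 5 seeds) as the separation dial grows."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        from bbscore.preprocessing import downsample, minmax_normalize

        def mean_acc(separation):
            accs = []
            for seed in range(5):
                cfg = _cfg(
                    task_ids=(1,),
                    class_counts={s: 8 for s in range(5)},
                    separation=separation,
                    seed=seed,
                )
                ds = downsample(minmax_normalize(generate_task_dataset(cfg, 1)), 20.0)
                X = ds.samples.reshape(len(ds), -1)
                clf = LogisticRegression(max_iter=500)
                accs.append(cross_val_score(clf, X, ds.labels, cv=4).mean())
            return np.mean(accs)

        accuracies = [mean_acc(s) for s in (0.0, 1.0, 2.5)]
        assert accuracies[1] >= accuracies[0] - 0.02
        assert accuracies[2] >= accuracies[1] - 0.02
        assert accuracies[2] > accuracies[0]


class TestRoundTrip:
    def test_csv_round_trip(self, tmp_path):
        cfg = _cfg(task_ids=(1,))
        rec, anns = generate_recording(cfg, 0)
        write_recording_csv(rec, anns, tmp_path / "subj0")
        rec2, anns2 = read_recording_csv(tmp_path / "subj0")
        np.testing.assert_allclose(rec2.data, rec.data, rtol=1e-9, atol=1e-12)
        assert rec2.sampling_rate_hz == rec.sampling_rate_hz
        assert anns2 == anns

    def test_missing_column_rejected(self, tmp_path):
        cfg = _cfg(task_ids=(1,))
        rec, anns = generate_recording(cfg, 0)
        csv_path, _ = write_recording_csv(rec, anns, tmp_path / "s")
        lines = csv_path.read_text().splitlines()
        header = lines[0].split(",")
        drop = header.index("B_Acz")
        mutated = "\n".join(
            ",".join(v for i, v in enumerate(line.split(",")) if i != drop)
            for line in lines
        )
        csv_path.write_text(mutated)
        with pytest.raises(RecordingParseError, match="header"):
            read_recording_csv(tmp_path / "s")

    def test_non_numeric_cell_names_column_and_row(self, tmp_path):
        cfg = _cfg(task_ids=(1,))
        rec, anns = generate_recording(cfg, 0)
        csv_path, _ = write_recording_csv(rec, anns, tmp_path / "s")
        lines = csv_path.read_text().splitlines()
        cells = lines[3].split(",")
        cells[1] = "oops"
        lines[3] = ",".join(cells)
        csv_path.write_text("\n".join(lines))
        with pytest.raises(RecordingParseError, match="FH_Acx.*row 2"):
            read_recording_csv(tmp_path / "s")

    def test_out_of_range_annotation_rejected(self, tmp_path):
        cfg = _cfg(task_ids=(1,))
        rec, anns = generate_recording(cfg, 0)
        _, ann_path = write_recording_csv(rec, anns, tmp_path / "s")
        import json

        payload = json.loads(ann_path.read_text())
        payload[0]["end_index"] = rec.n_samples + 10
        ann_path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="exceeds"):
            read_recording_csv(tmp_path / "s")
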
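"""Cutoff scanning and recovery metrics."""

import math
import warnings

import numpy as np
import pytest

from cutofflens import (
    AnnotationSet,
    evaluate,
    fraction_recovered,
    scan_cutoffs,
    sequence_distance,
)
from cutofflens.scan import aggregate, metrics_frame


class TestSequenceDistance:
    def test_same_chain(self, globule40):
        assert sequence_distance(10, 12, globule40) == 2
        assert sequence_distance(7, 7, globule40) == 0

    def test_cross_chain_is_infinite(self, dimer30):
        assert math.isinf(sequence_distance(5, 35, dimer30))
        assert sequence_distance(5, 7, dimer30) == 2


class TestFractionRecovered:
    def test_adjacent_peak(self, globule40):
        assert fraction_recovered({11}, {10}, 1, globule40) == 1.0
        assert fraction_recovered({11}, {10}, 0, globule40) == 0.0

    def test_exact_peaks_recover_everything(self, globule40):
        catalytic = {3, 17, 25}
        for dn in (0, 1, 5):
            assert fraction_recovered(catalytic, catalytic, dn, globule40) == 1.0

    def test_partial_recovery_hand_computed(self, globule40):
        # distances to peak {7}: 2 and 18
        assert fraction_recovered({7}, {5, 25}, 2, globule40) == 0.5

    def test_no_catalytic_raises(self, globule40):
        with pytest.raises(ValueError):
            fraction_recovered({1}, set(), 0, globule40)

    def test_monotone_in_dn_and_peaks(self, globule40):
        rng = np.random.Generator(np.random.PCG64(11))
        catalytic = set(rng.choice(40, size=5, replace=False).tolist())
        peaks = set(rng.choice(40, size=4, replace=False).tolist())
        fracs = [fraction_recovered(peaks, catalytic, dn, globule40) for dn in range(6)]
        assert fracs == sorted(fracs)
        more = fraction_recovered(peaks | {0, 20}, catalytic, 2, globule40)
        assert more >= fracs[2]


@pytest.fixture(scope="module")
def scan(planted_hub):
    s, _, _ = planted_hub
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return scan_cutoffs(s, cutoffs=[8.0, 14.0, 22.0])


class TestScanCutoffs:

    def test_bookkeeping(self, scan):
        assert len(scan.reduced) == 3 * 3
        assert scan.cutoffs == [8.0, 14.0, 22.0]
        assert not scan.errors

    def test_connectivity_status_recorded(self, scan):
        assert set(scan.connected) == {8.0, 14.0, 22.0}
        assert scan.connected[22.0] is True

    def test_invalid_grid_rejected(self, globule40):
        with pytest.raises(ValueError):
            scan_cutoffs(globule40, cutoffs=[10.0, 8.0])

    def test_fully_connected_limit_blurs_graph_indicators(self, globule40):
        c = globule40.coords()
        diameter = np.linalg.norm(c[:, None] - c[None, :], axis=2).max()
        sr = scan_cutoffs(globule40, cutoffs=[float(np.ceil(diameter))])
        cutoff = sr.cutoffs[0]
        assert sr.reduced[(cutoff, "conn")].n_peaks == 0
        assert sr.reduced[(cutoff, "cc")].n_peaks == 0


class TestEvaluate:
    def test_metric_arithmetic(self, planted_hub):
        s, ann, hub = planted_hub
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sr = scan_cutoffs(s, cutoffs=[10.0, 22.0])
            metrics = evaluate(sr, s, ann, dn_list=[0, 1, 2])
        n = len(s)
        for (cutoff, ind), m in metrics.items():
            rp = sr.reduced[(cutoff, ind)]
            assert m.peak_fraction == pytest.approx(rp.n_peaks / n)
            assert m.n_catalytic == 1
            fr = [m.frac_within[d] for d in (0, 1, 2)]
            assert fr == sorted(fr)
            for d in (0, 1, 2):
                if rp.n_peaks:
                    assert m.reliability[d] == pytest.approx(
                        m.frac_within[d] / m.peak_fraction
                    )
                else:
                    assert m.reliability[d] is None

    def test_single_perfect_peak(self, globule40):
        """peaks {10} on N=40, catalytic {10}: reliability = N."""
        sr = scan_cutoffs(globule40, cutoffs=[12.0])
        rp = sr.reduced[(12.0, "chi")]
        rp.peaks = [10]
        rp.filtered = np.zeros(len(globule40))
        rp.filtered[10] = 1.0
        ann = AnnotationSet(
            globule40.structure_id, {("A", globule40.residues[10].res_seq, "")}
        )
        m = evaluate(sr, globule40, ann, dn_list=[0])[(12.0, "chi")]
        assert m.frac_within[0] == 1.0
        assert m.peak_fraction == pytest.approx(1 / 40)
        assert m.reliability[0] == pytest.approx(40.0)
        assert m.peaks_per_site == 1.0

    def test_metrics_frame_shape(self, planted_hub):
        s, ann, _ = planted_hub
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sr = scan_cutoffs(s, cutoffs=[10.0])
            metrics = evaluate(sr, s, ann, dn_list=[0, 1])
        df = metrics_frame(metrics, s.structure_id)
        assert len(df) == 3 * 2  # indicators x dn
        assert set(df.columns) >= {"cutoff", "indicator", "dn", "frac_within"}


class TestAggregate:
    def _dataset(self, seeds):
        from cutofflens import make_planted_hub

        out = []
        for seed in seeds:
            s, ann, _ = make_planted_hub(seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sr = scan_cutoffs(s, cutoffs=[10.0, 22.0])
            out.append((s, sr, ann))
        return out

    def test_single_structure_matches_own_metrics(self, planted_hub):
        s, ann, _ = planted_hub
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sr = scan_cutoffs(s, cutoffs=[10.0, 22.0])
            pooled = aggregate([(s, sr, ann)], dn_list=[1])["overall"]
            metrics = evaluate(sr, s, ann, dn_list=[1])
        for (cutoff, ind), m in metrics.items():
            row = pooled[(pooled.cutoff == cutoff) & (pooled.indicator == ind)]
            assert row.frac_within.iloc[0] == pytest.approx(m.frac_within[1])

    def test_pooled_fraction_weighs_by_site_count(self, planted_hub):
        s, ann, hub = planted_hub
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sr = scan_cutoffs(s, cutoffs=[22.0])
        # second pseudo-structure: same scan, annotation far from any peak
        far = AnnotationSet(s.structure_id, {("A", s.residues[-1].res_seq, "")})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pooled = aggregate(
                [(s, sr, ann), (s, sr, far)], dn_list=[0]
            )["overall"]
        chi = pooled[(pooled.indicator == "chi")]
        # two structures with equal N_c: pooled = mean of the two fractions
        assert chi.n_catalytic.iloc[0] == 2

    def test_size_classes_partition(self):
        dataset = self._dataset([0, 1, 2])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curves = aggregate(dataset, dn_list=[1], size_classes=[120, 150])
        overall = curves["overall"]
        class_counts = [
            df.n_structures.iloc[0] for label, df in curves.items()
            if label != "overall"
        ]
        assert sum(class_counts) == overall.n_structures.iloc[0]

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            aggregate([], dn_list=[1])
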
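"""Splicing-map construction: occupancy profiles, PSI-matched resampling,
z-score computation and its calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clipmap.io import CrosslinkTrack
from clipmap.splicing_events import filter_significant_events, read_ce_table
from clipmap.splicing_map import (
    ANCHORS, build_splicing_map, exon_crosslink_density, occupancy_matrix,
    occupancy_profile, psi_matched_sample, splice_site_anchors,
)

from _oracles import oracle_bh


def tiny_events(n=3, strand="+", chrom="toy", spacing=1000):
    rows = []
    for i in range(n):
        base = 500 + i * spacing
        if strand == "+":
            up = (base, base + 100)
            alt = (base + 300, base + 400)
            down = (base + 700, base + 800)
        else:
            down = (base, base + 100)
            alt = (base + 300, base + 400)
            up = (base + 700, base + 800)
        rows.append({
            "event_id": f"e{i}", "gene_id": f"G{i}", "chrom": chrom,
            "strand": strand,
            "exon_start": alt[0], "exon_end": alt[1],
            "up_start": up[0], "up_end": up[1],
            "down_start": down[0], "down_end": down[1],
            "psi_ctl_mean": 0.5,
        })
    return pd.DataFrame(rows)


class TestAnchors:
    def test_plus_strand(self):
        ev = tiny_events(1).iloc[0]
        anchors = splice_site_anchors(ev)
        assert anchors["up_3ss"] == 500 and anchors["up_5ss"] == 599
        assert anchors["alt_3ss"] == 800 and anchors["alt_5ss"] == 899

    def test_minus_strand_mirrored(self):
        ev = tiny_events(1, strand="-").iloc[0]
        anchors = splice_site_anchors(ev)
        assert anchors["up_3ss"] == 1299 and anchors["up_5ss"] == 1200
        assert anchors["down_3ss"] == 599 and anchors["down_5ss"] == 500


class TestOccupancy:
    def test_empty_track_gives_zero(self):
        track = CrosslinkTrack({"toy": 5000})
        prof = occupancy_profile(tiny_events(), track)
        assert (prof.to_numpy() == 0).all()

    def test_every_event_hit_at_offset_zero(self):
        track = CrosslinkTrack({"toy": 5000})
        events = tiny_events()
        for ev in events.itertuples(index=False):
            track.data[("toy", "+")][splice_site_anchors(ev)["alt_3ss"]] = 3
        prof = occupancy_profile(events, track)
        assert prof.loc["alt_3ss", 0] == 1.0

    def test_matches_per_event_bruteforce(self):
        rng = np.random.default_rng(8)
        track = CrosslinkTrack({"toy": 5000})
        for strand in "+-":
            track.data[("toy", strand)] = rng.poisson(0.2, size=5000).astype(np.int64)
        for strand in "+-":
            events = tiny_events(strand=strand)
            mat = occupancy_matrix(events, track, window=50)
            for i, ev in enumerate(events.itertuples(index=False)):
                anchors = splice_site_anchors(ev)
                for a, name in enumerate(ANCHORS):
                    for j, off in enumerate(range(-50, 51)):
                        pos = anchors[name] + (off if strand == "+" else -off)
                        expect = track.data[("toy", strand)][pos] > 0
                        assert mat[i, a, j] == expect


class TestPsiMatching:
    def test_self_pool_preserves_mean(self):
        rng = np.random.default_rng(1)
        psi = rng.uniform(0, 1, size=200)
        idx = psi_matched_sample(psi, psi, rng=np.random.default_rng(2))
        assert len(idx) == 200
        assert abs(psi[idx].mean() - psi.mean()) < 0.02

    def test_concentrated_set_matched_from_uniform_pool(self):
        rng = np.random.default_rng(1)
        reg = rng.normal(0.9, 0.01, size=500).clip(0, 1)
        pool = rng.uniform(0, 1, size=20000)
        idx = psi_matched_sample(reg, pool, rng=np.random.default_rng(3))
        assert abs(pool[idx].mean() - reg.mean()) < 0.02

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        reg = rng.uniform(0.3, 0.8, size=100)
        pool = rng.uniform(0, 1, size=5000)
        a = psi_matched_sample(reg, pool, rng=np.random.default_rng(7))
        b = psi_matched_sample(reg, pool, rng=np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_insufficient_bin_warns_and_fills(self):
        reg = np.full(50, 0.95)
        pool = np.full(3, 0.95)
        with pytest.warns(UserWarning, match="with replacement"):
            idx = psi_matched_sample(reg, pool, rng=np.random.default_rng(0))
        assert len(idx) == 50


class TestMapStatistics:
    def test_z_equals_spreadsheet_recomputation_on_micro_instance(self):
        """3 events, tiny window: z at every position equals an explicit
        mean/sd/tail recomputation from the same background profiles."""
        rng = np.random.default_rng(21)
        track = CrosslinkTrack({"toy": 20000})
        for strand in "+-":
            track.data[("toy", strand)] = rng.poisson(0.3, size=20000).astype(np.int64)
        events = tiny_events(3)
        pool = tiny_events(12, spacing=1200).assign(
            psi_ctl_mean=np.linspace(0.2, 0.8, 12))
        window, n_iter, seed = 2, 8, 5
        map_df = build_splicing_map({"down": events}, pool, track,
                                    window=window, n_iter=n_iter, seed=seed)
        # independent recomputation, replaying the sampling stream
        obs = occupancy_matrix(events, track, window).mean(axis=0)
        pool_mat = occupancy_matrix(pool, track, window)
        rng2 = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        profiles = []
        for _ in range(n_iter):
            idx = psi_matched_sample(events["psi_ctl_mean"].to_numpy(),
                                     pool["psi_ctl_mean"].to_numpy(), rng=rng2)
            profiles.append(pool_mat[idx].mean(axis=0))
        profiles = np.array(profiles)
        mu = profiles.mean(axis=0)
        sd = profiles.std(axis=0, ddof=1)
        p_expect = np.ones_like(mu)
        z_expect = np.zeros_like(mu)
        nz = sd > 0
        z_expect[nz] = (obs[nz] - mu[nz]) / sd[nz]
        p_expect[nz] = stats.norm.sf(z_expect[nz])
        adj_expect = np.array(oracle_bh(p_expect.ravel())).reshape(p_expect.shape)
        for a, anchor in enumerate(ANCHORS):
            sub = map_df[(map_df["anchor"] == anchor)].sort_values("offset")
            assert np.allclose(sub["z"].to_numpy(), z_expect[a], atol=1e-12)
            assert np.allclose(sub["p_adj"].to_numpy(), adj_expect[a], atol=1e-12)

    def test_sd_zero_positions_flagged_not_significant(self):
        track = CrosslinkTrack({"toy": 20000})  # empty track -> sd 0 everywhere
        events = tiny_events(3)
        pool = tiny_events(10, spacing=1200).assign(psi_ctl_mean=0.5)
        map_df = build_splicing_map({"down": events}, pool, track,
                                    window=5, n_iter=4, seed=0)
        assert map_df["sd_zero"].all()
        assert (map_df["z"] == 0).all() and (map_df["p"] == 1).all()
        assert not map_df["significant"].any()

    def test_z_scores_stable_across_resampling_seeds(self, default_dataset, tmp_path):
        """With 50 background iterations, positionwise z-scores from two
        different resampling seeds correlate > 0.95."""
        ds = default_dataset
        path = tmp_path / "ce.tsv"
        ds.ce_table.to_csv(path, sep="\t", index=False)
        sets = filter_significant_events(read_ce_table(path))
        maps = [build_splicing_map({"down": sets.down}, sets.unchanged,
                                   ds.merged_track, n_iter=50, seed=s)
                for s in (101, 202)]
        z0 = maps[0].sort_values(["anchor", "offset"])["z"].to_numpy()
        z1 = maps[1].sort_values(["anchor", "offset"])["z"].to_numpy()
        assert np.corrcoef(z0, z1)[0, 1] > 0.95

    def test_null_calibration(self, default_dataset, tmp_path):
        """A 'regulated' set drawn from the background pool itself shows at
        most the nominal rate of significant positions."""
        ds = default_dataset
        path = tmp_path / "ce.tsv"
        ds.ce_table.to_csv(path, sep="\t", index=False)
        sets = filter_significant_events(read_ce_table(path))
        pool = sets.unchanged
        rng = np.random.default_rng(17)
        fake = pool.iloc[rng.choice(len(pool), size=60, replace=False)]
        rest = pool.drop(fake.index)
        map_df = build_splicing_map({"null": fake.reset_index(drop=True)},
                                    rest.reset_index(drop=True),
                                    ds.merged_track, n_iter=50, seed=3)
        rate = map_df["significant"].mean()
        mc = 2 * np.sqrt(0.05 * 0.95 / len(map_df))
        assert rate <= 0.05 + mc


class TestDensity:
    def test_formula(self):
        track = CrosslinkTrack({"toy": 1000})
        assert exon_crosslink_density("toy", "+", 0, 100, track) == pytest.approx(
            np.log2(1 / 100))
        track.data[("toy", "+")][10] = 7
        assert exon_crosslink_density("toy", "+", 0, 100, track) == pytest.approx(
            np.log2(8 / 100))

    def test_density_increases_with_inclusion(self, default_dataset):
        """Exons with higher control inclusion accumulate more crosslink
        events per nt — the coverage bias motivating PSI matching."""
        ds = default_dataset
        rows = []
        for plan in ds.plans[ds.plans["klass"] == "neutral"].itertuples(index=False):
            from clipmap.synthetic import transcript_exons
            alt = transcript_exons(ds.annotation, plan.gene_id)[plan.alt_idx]
            rows.append({
                "psi": plan.psi0,
                "density": exon_crosslink_density(plan.chrom, plan.strand,
                                                  alt[0], alt[1], ds.merged_track),
            })
        df = pd.DataFrame(rows)
        df["bin"] = pd.qcut(df["psi"], 5, labels=False)
        medians = df.groupby("bin")["density"].median()
        assert medians.is_monotonic_increasing
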
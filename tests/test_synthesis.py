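"""Synthetic page generation: selection filters, rendering, rotation,
composition and dataset determinism."""

import hashlib

import numpy as np
import pytest
from scipy.stats import chisquare

from chemseg.library import MoleculeSpec, annotate_smiles
from chemseg.synthesis import (
    BACKGROUND_THRESHOLD,
    NoEligibleMoleculesError,
    PageMaskPair,
    PlacementError,
    RenderedDepiction,
    SynthesisConfig,
    compose_page,
    generate_dataset,
    render_depiction,
    rotate_depiction,
    select_cluster_record,
    select_single_molecules,
    synthesize_pages,
)


def spec(i, smiles="CCO", heavy=3, total=9, cluster=False):
    s = smiles if not cluster else smiles + ".C"
    return MoleculeSpec(id=f"m{i}", smiles=s, heavy_atoms=heavy, total_atoms=total)


# ------------------------------------------------------------- selection

class TestSelection:
    def test_heavy_atom_window_is_inclusive(self):
        lib = [spec(i, heavy=h) for i, h in enumerate([10, 15, 28, 40])]
        cfg = SynthesisConfig()
        rng = np.random.default_rng(0)
        got = {
            m.heavy_atoms
            for _ in range(50)
            for m in select_single_molecules(lib, cfg, rng)
        }
        assert got == {15, 28}

    def test_sampling_without_replacement(self):
        lib = [spec(i, heavy=20) for i in range(5)]
        picked = select_single_molecules(
            lib, SynthesisConfig(), np.random.default_rng(0), n=3
        )
        assert len(picked) == 3
        assert len({m.id for m in picked}) == 3

    def test_no_eligible_molecules_is_an_error(self):
        lib = [spec(0, heavy=5)]
        with pytest.raises(NoEligibleMoleculesError):
            select_single_molecules(lib, SynthesisConfig(), np.random.default_rng(0))

    def test_eligible_count_matches_bruteforce_on_packaged_library(self, library):
        cfg = SynthesisConfig()
        eligible = {
            m.id
            for m in library
            if not m.is_multi_fragment and 15 <= m.heavy_atoms <= 28
        }
        rng = np.random.default_rng(1)
        seen = set()
        for _ in range(300):
            seen |= {m.id for m in select_single_molecules(library, cfg, rng)}
        assert seen == eligible

    def test_cluster_total_atom_window_is_inclusive(self):
        lib = [
            spec(i, cluster=True, total=t) for i, t in enumerate([249, 250, 300, 301])
        ]
        rng = np.random.default_rng(0)
        got = {
            select_cluster_record(lib, SynthesisConfig(), rng).total_atoms
            for _ in range(100)
        }
        assert got == {250, 300}

    def test_single_eligible_cluster_forced(self):
        lib = [spec(0, cluster=True, total=275)]
        for s in range(5):
            rec = select_cluster_record(lib, SynthesisConfig(), np.random.default_rng(s))
            assert rec.id == "m0"

    def test_cluster_selection_uniform_over_eligible(self):
        lib = [spec(i, cluster=True, total=260 + i) for i in range(5)]
        rng = np.random.default_rng(42)
        counts = {m.id: 0 for m in lib}
        for _ in range(1000):
            counts[select_cluster_record(lib, SynthesisConfig(), rng).id] += 1
        _, p = chisquare(list(counts.values()))
        assert p > 0.01


# ------------------------------------------------------------- rendering

class TestRendering:
    def test_methane_renders_ink(self):
        dep = render_depiction(annotate_smiles("methane", "C"), thickness=1)
        assert dep.ink_mask.sum() > 0
        assert dep.bitmap.shape == dep.ink_mask.shape

    def test_thicker_lines_mean_more_ink(self):
        mol = annotate_smiles("benzene", "c1ccccc1")
        thin = render_depiction(mol, thickness=1)
        thick = render_depiction(mol, thickness=3)
        assert thick.ink_mask.sum() > thin.ink_mask.sum()

    def test_ink_mask_is_below_background_everywhere(self):
        dep = render_depiction(annotate_smiles("aspirin", "CC(=O)Oc1ccccc1C(=O)O"), 2)
        np.testing.assert_array_equal(
            dep.ink_mask, (dep.bitmap < BACKGROUND_THRESHOLD).astype(np.uint8)
        )

    def test_depiction_failure_carries_molecule_id(self):
        from chemseg.synthesis import DepictionError

        bad = MoleculeSpec(id="broken", smiles="((", heavy_atoms=1, total_atoms=1)
        with pytest.raises(DepictionError) as err:
            render_depiction(bad, 1)
        assert err.value.molecule_id == "broken"


class TestRotation:
    def test_zero_angle_is_identity(self):
        dep = render_depiction(annotate_smiles("tol", "Cc1ccccc1"), 2)
        rot = rotate_depiction(dep, 0.0)
        np.testing.assert_array_equal(rot.bitmap, dep.bitmap)

    def test_ink_count_preserved_within_tolerance(self):
        dep = render_depiction(annotate_smiles("nap", "c1ccc2ccccc2c1"), 2)
        before = int(dep.ink_mask.sum())
        for angle in (7.5, 15.0, 30.0):
            after = int(rotate_depiction(dep, angle).ink_mask.sum())
            assert abs(after - before) <= 0.10 * before

    def test_rotated_bar_height_follows_trigonometry(self):
        bar = np.full((1, 20), 100, dtype=np.uint8)
        dep = RenderedDepiction(
            bitmap=bar, ink_mask=np.ones((1, 20), dtype=np.uint8)
        )
        rot = rotate_depiction(dep, 30.0)
        rows = np.any(rot.ink_mask, axis=1)
        height = rows.nonzero()[0].max() - rows.nonzero()[0].min() + 1
        assert height >= 20 * np.sin(np.deg2rad(30.0))

    @pytest.mark.parametrize("angle", [-1.0, 30.5, 180.0])
    def test_angle_out_of_range_rejected(self, angle):
        dep = RenderedDepiction(
            bitmap=np.full((4, 4), 255, np.uint8), ink_mask=np.zeros((4, 4), np.uint8)
        )
        with pytest.raises(ValueError):
            rotate_depiction(dep, angle)


# ----------------------------------------------------------- composition

def _white_page(cfg):
    return np.full(cfg.page_size, 255, dtype=np.uint8)


def _block_dep(i, side=40):
    bitmap = np.full((side, side), 0, dtype=np.uint8)
    return RenderedDepiction(
        bitmap=bitmap, ink_mask=np.ones((side, side), np.uint8), asset_id=f"b{i}"
    )


class TestComposition:
    def test_empty_composition(self):
        cfg = SynthesisConfig()
        pair = compose_page(_white_page(cfg), [], cfg, np.random.default_rng(0))
        assert pair.mask.sum() == 0
        np.testing.assert_array_equal(pair.page, _white_page(cfg))

    def test_single_molecule_mask_count(self):
        cfg = SynthesisConfig(grid_prob=0.0)
        dep = render_depiction(annotate_smiles("ibu", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"), 2)
        pair = compose_page(
            _white_page(cfg), [("molecule", dep)], cfg, np.random.default_rng(0)
        )
        assert pair.mask.sum() == dep.ink_mask.sum()

    def test_eight_assets_pairwise_disjoint_bruteforce(self):
        cfg = SynthesisConfig(grid_prob=0.0)
        assets = [("molecule", _block_dep(i)) for i in range(6)] + [
            ("negative", _block_dep(i + 6, side=30)) for i in range(2)
        ]
        pair = compose_page(_white_page(cfg), assets, cfg, np.random.default_rng(3))
        boxes = [p.bbox for p in pair.placements]
        assert len(boxes) == 8
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                a, b = boxes[i], boxes[j]
                overlap = not (
                    a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1]
                )
                assert not overlap, (a, b)

    def test_impossible_placement_names_the_asset(self):
        cfg = SynthesisConfig()
        huge = _block_dep(0, side=600)
        with pytest.raises(PlacementError) as err:
            compose_page(_white_page(cfg), [("molecule", huge)], cfg,
                         np.random.default_rng(0))
        assert err.value.asset_id == "b0"


# --------------------------------------------------------------- dataset

class TestDataset:
    def test_zero_pages_gives_empty_manifest(self, tmp_path):
        manifest = generate_dataset(SynthesisConfig(n_pages=0), tmp_path)
        assert manifest == []

    def test_same_seed_bitwise_identical(self, tmp_path):
        cfg = SynthesisConfig(n_pages=3, seed=5)
        generate_dataset(cfg, tmp_path / "a")
        generate_dataset(cfg, tmp_path / "b")
        for sub in ("pages/0000.png", "masks/0002.png", "manifest.jsonl"):
            ha = hashlib.sha256((tmp_path / "a" / sub).read_bytes()).hexdigest()
            hb = hashlib.sha256((tmp_path / "b" / sub).read_bytes()).hexdigest()
            assert ha == hb, sub

    def test_mask_is_exact_union_of_molecule_ink(self, ten_pages):
        for pair in ten_pages:
            union = np.zeros_like(pair.mask)
            for r0, c0, ink in pair.molecule_inks:
                h, w = ink.shape
                union[r0 : r0 + h, c0 : c0 + w] |= ink
            np.testing.assert_array_equal(pair.mask, union)

    def test_page_bounds_counts_and_rotations(self, ten_pages):
        for pair in ten_pages:
            mols = [p for p in pair.placements if p.kind == "molecule"]
            if pair.route == "single":
                assert 1 <= len(mols) <= 6
            assert all(0.0 <= p.angle <= 30.0 for p in mols)
            h, w = pair.page.shape
            for p in pair.placements:
                r0, c0, r1, c1 = p.bbox
                assert 0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w

    def test_non_molecule_ink_never_in_mask(self, ten_pages):
        """Grid lines, negatives and text land on the page but not the mask."""
        for pair in ten_pages:
            page_ink = pair.page < 250
            assert page_ink[pair.mask > 0].all()
            for p in pair.placements:
                if p.kind != "molecule":
                    r0, c0, r1, c1 = p.bbox
                    assert pair.mask[r0:r1, c0:c1].sum() == 0
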
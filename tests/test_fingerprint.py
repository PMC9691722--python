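"""Percent-response PWM construction, peptide scoring, score->K_D mapping."""

import math

import numpy as np
import pandas as pd
import pytest

from tcrspec.constants import AMINO_ACIDS, AA_INDEX, rt
from tcrspec.errors import IncompleteLibraryError, InvalidParameterError, MotifError
from tcrspec.fingerprint import (
    VARIED_POSITIONS,
    WT_SEQUENCE,
    ScanLibrary,
    SpecificityFingerprint,
    anchor_dg_wt,
    build_fingerprint,
    kd_from_score,
    read_library_csv,
    score_peptide,
    write_library_csv,
)


def flat_library(dg_wt=-6.3, special=None):
    """Library with every cell at dg_wt except the cells in ``special``."""
    special = special or {}
    rows = [
        (p, a, special.get((p, a), dg_wt), 0.0)
        for p in VARIED_POSITIONS
        for a in AMINO_ACIDS
    ]
    return ScanLibrary(
        entries=pd.DataFrame(rows, columns=["position", "amino_acid", "dg", "dg_err"]),
        wt_replicates=[dg_wt] * 7,
    )


class TestBuildFingerprint:
    def test_single_weak_cell_construction(self):
        # all cells at dg_wt, one weakest cell: WT cells -> 100, norm 700
        lib = flat_library(special={(3, "A"): -4.0})
        fp = build_fingerprint(lib)
        for row, pos in enumerate(VARIED_POSITIONS):
            assert fp.percent[row, AA_INDEX[WT_SEQUENCE[pos - 1]]] == 100.0
        assert fp.norm_factor == 700.0
        assert fp.percent[VARIED_POSITIONS.index(3), AA_INDEX["A"]] == 0.0

    def test_midpoint_cell_is_fifty(self):
        lib = flat_library(special={(3, "A"): -4.0, (5, "W"): -5.15})
        fp = build_fingerprint(lib)
        assert fp.percent[VARIED_POSITIONS.index(5), AA_INDEX["W"]] == pytest.approx(50.0)

    def test_matrix_matches_hand_transform(self, noise_free_library):
        lib, truth = noise_free_library
        fp = build_fingerprint(lib)
        # independent recomputation from the raw table via pandas
        cells = truth[truth.position > 0]
        lo, hi = cells.dg_measured.min(), cells.dg_measured.max()
        pivot = cells.pivot(index="position", columns="amino_acid",
                            values="dg_measured")
        expected = 100.0 * (hi - pivot) / (hi - lo)
        np.testing.assert_allclose(
            fp.percent,
            expected.loc[list(VARIED_POSITIONS), list(AMINO_ACIDS)].to_numpy(),
            rtol=1e-12,
        )
        assert fp.percent.max() == 100.0
        assert fp.percent.min() == 0.0

    def test_literal_orientation_inverts_scale(self, noise_free_library):
        lib, _ = noise_free_library
        fp = build_fingerprint(lib)
        lit = build_fingerprint(lib, orientation="literal")
        np.testing.assert_allclose(lit.percent, 100.0 - fp.percent, atol=1e-9)

    def test_dg_wt_defaults_to_replicate_mean(self, noise_free_library):
        lib, _ = noise_free_library
        fp = build_fingerprint(lib)
        assert fp.dg_wt == pytest.approx(np.mean(lib.wt_replicates))

    def test_replicate_mean_cell_policy_keeps_wt_score_one(self, noisy_library):
        lib, _ = noisy_library
        fp = build_fingerprint(lib, wt_cell_policy="replicate-mean")
        assert score_peptide(fp, WT_SEQUENCE).score == 1.0

    def test_incomplete_library_lists_gaps(self):
        lib = flat_library(special={(3, "A"): -4.0})
        lib.entries = lib.entries[
            ~((lib.entries.position == 5) & (lib.entries.amino_acid == "K"))
        ]
        with pytest.raises(IncompleteLibraryError, match=r"\(5, 'K'\)"):
            build_fingerprint(lib)

    def test_degenerate_library_rejected(self):
        with pytest.raises(InvalidParameterError, match="degenerate"):
            build_fingerprint(flat_library())


class TestScorePeptide:
    def test_wild_type_scores_exactly_one(self, fingerprint_noise_free):
        assert score_peptide(fingerprint_noise_free, WT_SEQUENCE).score == 1.0

    def test_wild_type_scores_one_on_noisy_library(self, fingerprint_noisy):
        assert score_peptide(fingerprint_noisy, WT_SEQUENCE).score == 1.0

    def test_best_cell_peptide_attains_max_score(self, fingerprint_noise_free):
        fp = fingerprint_noise_free
        pep = list(WT_SEQUENCE)
        for row, pos in enumerate(fp.varied_positions):
            pep[pos - 1] = AMINO_ACIDS[int(np.argmax(fp.percent[row]))]
        ps = score_peptide(fp, "".join(pep))
        assert ps.score == pytest.approx(fp.max_score(), rel=1e-12)

    def test_score_equals_brute_force_sum(self, fingerprint_noise_free):
        fp = fingerprint_noise_free
        rng = np.random.default_rng(3)
        for _ in range(20):
            pep = list(WT_SEQUENCE)
            for pos in fp.varied_positions:
                pep[pos - 1] = AMINO_ACIDS[rng.integers(20)]
            pep = "".join(pep)
            expected = math.fsum(
                fp.percent[row, AA_INDEX[pep[pos - 1]]]
                for row, pos in enumerate(fp.varied_positions)
            ) / fp.norm_factor
            assert score_peptide(fp, pep).score == pytest.approx(expected, rel=1e-12)

    def test_weakening_a_cell_never_raises_scores(self, noise_free_library):
        lib, _ = noise_free_library
        fp = build_fingerprint(lib)
        weakened = lib.entries.copy()
        target = (weakened.position == 1) & (weakened.amino_acid == "F")
        weakened.loc[target, "dg"] += 1.0  # weaker binding
        fp2 = build_fingerprint(
            ScanLibrary(entries=weakened, wt_replicates=lib.wt_replicates)
        )
        # the perturbed cell must stay interior so the percent range is fixed
        assert fp2.dg_strongest == fp.dg_strongest
        assert fp2.dg_weakest == fp.dg_weakest
        rng = np.random.default_rng(4)
        for _ in range(50):
            pep = list(WT_SEQUENCE)
            for pos in fp.varied_positions:
                pep[pos - 1] = AMINO_ACIDS[rng.integers(20)]
            pep[0] = "F"  # force use of the weakened cell
            pep = "".join(pep)
            assert score_peptide(fp2, pep).score <= score_peptide(fp, pep).score + 1e-12

    @pytest.mark.parametrize(
        "peptide",
        ["YMDGTMSQ", "YMDGTMSQVV", "YADGTMSQV", "YMDGTMSQA", "YMXGTMSQV"],
    )
    def test_motif_violations_rejected(self, fingerprint_noise_free, peptide):
        with pytest.raises(MotifError):
            score_peptide(fingerprint_noise_free, peptide)

    def test_leucine_anchor_allowed_when_requested(self, fingerprint_noise_free):
        pep = "YLDGTMSQV"
        with pytest.raises(MotifError):
            score_peptide(fingerprint_noise_free, pep)
        ps = score_peptide(fingerprint_noise_free, pep, allowed_p2={"M", "L"})
        # p2 is an anchor: it contributes nothing, so the score matches WT
        assert ps.score == 1.0


class TestKdFromScore:
    DG_WT = rt() * math.log(2.5e-5)

    def test_identity_at_score_one(self):
        assert kd_from_score(1.0, self.DG_WT) == pytest.approx(2.5e-5, rel=1e-12)

    def test_standard_state_at_score_zero(self):
        assert kd_from_score(0.0, self.DG_WT) == 1.0

    def test_square_root_at_half_score(self):
        assert kd_from_score(0.5, self.DG_WT) == pytest.approx(5.0e-3, rel=1e-9)

    def test_power_law_consistency(self):
        k19 = kd_from_score(0.19, self.DG_WT)
        k50 = kd_from_score(0.5, self.DG_WT)
        assert k19 == pytest.approx(k50 ** (0.19 / 0.5), rel=1e-9)

    def test_monotone_decreasing_in_score(self):
        scores = np.linspace(0.0, 1.2, 25)
        kds = [kd_from_score(s, self.DG_WT) for s in scores]
        assert np.all(np.diff(kds) < 0)

    def test_positive_dg_wt_rejected(self):
        with pytest.raises(InvalidParameterError):
            kd_from_score(0.5, 1.0)

    def test_anchoring_from_known_pair(self):
        dg = anchor_dg_wt(0.5, 5e-3)
        assert kd_from_score(0.5, dg) == pytest.approx(5e-3, rel=1e-12)
        assert kd_from_score(1.0, dg) == pytest.approx(2.5e-5, rel=1e-9)


class TestLibraryIO:
    def test_csv_roundtrip(self, tmp_path, noise_free_library):
        lib, _ = noise_free_library
        path = tmp_path / "library.csv"
        write_library_csv(lib, path)
        back = read_library_csv(path)
        assert len(back) == 140
        assert back.wt_replicates == pytest.approx(lib.wt_replicates)
        merged = back.entries.merge(
            lib.entries, on=["position", "amino_acid"], suffixes=("_a", "_b")
        )
        assert len(merged) == 140
        np.testing.assert_allclose(merged.dg_a, merged.dg_b, rtol=1e-12)

    def test_kd_column_converted_to_dg(self, tmp_path):
        df = pd.DataFrame(
            {
                "position": [p for p in VARIED_POSITIONS for _ in AMINO_ACIDS],
                "amino_acid": list(AMINO_ACIDS) * len(VARIED_POSITIONS),
                "kd_M": 2.5e-5,
            }
        )
        path = tmp_path / "kd.csv"
        df.to_csv(path, index=False)
        lib = read_library_csv(path)
        assert lib.entries.dg.iloc[0] == pytest.approx(rt() * math.log(2.5e-5))

    def test_fingerprint_json_roundtrip(self, tmp_path, fingerprint_noise_free):
        path = tmp_path / "fp.json"
        fingerprint_noise_free.to_json(path)
        back = SpecificityFingerprint.from_json(path)
        np.testing.assert_allclose(back.percent, fingerprint_noise_free.percent)
        assert back.norm_factor == fingerprint_noise_free.norm_factor
        assert back.dg_wt == fingerprint_noise_free.dg_wt
        assert back.anchor_positions == fingerprint_noise_free.anchor_positions


class TestScanLibraryValidation:
    def test_anchor_position_entries_rejected(self):
        rows = [(2, "A", -5.0, 0.0)]
        with pytest.raises(InvalidParameterError, match="non-varied"):
            ScanLibrary(entries=pd.DataFrame(
                rows, columns=["position", "amino_acid", "dg", "dg_err"]))

    def test_duplicate_cells_rejected(self):
        rows = [(3, "A", -5.0, 0.0), (3, "A", -5.1, 0.0)]
        with pytest.raises(InvalidParameterError, match="duplicate"):
            ScanLibrary(entries=pd.DataFrame(
                rows, columns=["position", "amino_acid", "dg", "dg_err"]))

    def test_complete_library_has_140_members(self, noise_free_library):
        lib, _ = noise_free_library
        assert len(lib) == 140
        assert lib.is_complete()
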
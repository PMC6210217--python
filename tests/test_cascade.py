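"""Static filters, dotp/protein filters, curation rules, full cascade."""

import numpy as np
import pandas as pd
import pytest

from diaforge import masses, pipeline
from diaforge.cascade import (
    CurationSettings,
    apply_static_filter,
    dotp_filter,
    protein_min_peptides,
    run_cascade,
)
from diaforge.core import (
    AssayLibrary,
    Modification,
    Peptide,
    Precursor,
    Transition,
    ValidationError,
    census,
    count_missed_cleavages,
)


def _prec(seq, protein="P1", mods=None, n_trans=5, charge=2):
    pep = Peptide(
        sequence=seq,
        modifications=mods or [],
        missed_cleavages=count_missed_cleavages(seq),
        irt=50.0,
        protein_ids=[protein] if isinstance(protein, str) else list(protein),
    )
    mz = masses.peptide_mz(seq, charge, pep.mod_deltas())
    trans = [
        Transition("y", o, 1, masses.fragment_mz(seq, "y", o, 1, pep.mod_deltas()), 10.0 * (i + 1))
        for i, o in enumerate(range(3, 3 + n_trans))
    ]
    return Precursor(peptide=pep, charge=charge, mz=mz, decoy=False, transitions=trans)


class TestStaticFilters:
    def test_step1_disallowed_ptm(self):
        keep = _prec("AMDDEFGHK", mods=[Modification.oxidation(2)])
        drop = _prec("ASDDEFGHK", mods=[Modification.other(2, "Phospho", masses.MOD_DELTA["Phospho"])])
        lib = AssayLibrary([keep, drop])
        out = apply_static_filter(lib, 1)
        assert [p.peptide.sequence for p in out.precursors] == ["AMDDEFGHK"]

    def test_step2_shared_and_repeated(self):
        shared = _prec("AADDEFGHK", protein=("P1", "P2"))
        unique = _prec("CCDDEFGHK", protein="P3")
        lib = AssayLibrary([shared, unique])
        out = apply_static_filter(lib, 2)
        assert [p.peptide.sequence for p in out.precursors] == ["CCDDEFGHK"]
        # repeated: same sequence at two charges
        rep2 = _prec("EEDDFFGHK", charge=2)
        rep3 = _prec("EEDDFFGHK", charge=3)
        out = apply_static_filter(AssayLibrary([rep2, rep3, unique]), 2)
        assert [p.peptide.sequence for p in out.precursors] == ["CCDDEFGHK"]

    def test_step3_transition_floor_boundary(self):
        four = _prec("AADDEFGHK", n_trans=4)
        three = _prec("CCDDEFGHK", n_trans=3)
        out = apply_static_filter(AssayLibrary([four, three]), 3)
        assert [len(p.transitions) for p in out.precursors] == [4]

    def test_step4_missed_cleavages(self):
        clean = _prec("AADDEFGHK")
        missed = _prec("AAKDDEFGHK")
        out = apply_static_filter(AssayLibrary([clean, missed]), 4)
        assert [p.peptide.sequence for p in out.precursors] == ["AADDEFGHK"]

    def test_invalid_step(self):
        with pytest.raises(ValidationError):
            apply_static_filter(AssayLibrary(), 9)

    def test_idempotence(self):
        lib = AssayLibrary([_prec("AADDEFGHK"), _prec("CCDDEFGHK", n_trans=3)])
        for step in (1, 2, 3, 4):
            once = apply_static_filter(lib, step)
            twice = apply_static_filter(once, step)
            assert census(once) == census(twice)


class TestDotpFilter:
    def _lib(self):
        return AssayLibrary([_prec("AADDEFGHK"), _prec("CCDDEFGHK", protein="P2")])

    def _table(self, values):
        lib = self._lib()
        keys = [p.key_str for p in lib.precursors]
        return lib, pd.DataFrame(values, index=keys, columns=["s1", "s2", "s3"])

    def test_low_in_all_samples_removed(self):
        lib, tab = self._table([[0.79, 0.79, 0.79], [0.9, 0.9, 0.9]])
        out = dotp_filter(lib, tab)
        assert len(out.precursors) == 1

    def test_one_passing_sample_suffices(self):
        lib, tab = self._table([[0.85, 0.5, 0.5], [0.9, 0.9, 0.9]])
        assert len(dotp_filter(lib, tab).precursors) == 2

    def test_boundary_exactly_point_eight_kept(self):
        lib, tab = self._table([[0.80, 0.80, 0.80], [0.9, 0.9, 0.9]])
        assert len(dotp_filter(lib, tab).precursors) == 2

    def test_missing_coverage_rejected(self):
        lib = self._lib()
        tab = pd.DataFrame([[0.9, 0.9, 0.9]], index=[lib.precursors[0].key_str],
                           columns=["s1", "s2", "s3"])
        with pytest.raises(ValidationError, match="missing"):
            dotp_filter(lib, tab)


class TestProteinMinPeptides:
    def test_single_peptide_protein_removed(self):
        lib = AssayLibrary(
            [_prec("AADDEFGHK", "P1"), _prec("CCDDEFGHK", "P1"), _prec("EEDDFFGHK", "P2")]
        )
        out = protein_min_peptides(lib, 2)
        assert census(out).n_proteins == 1

    def test_two_peptides_kept(self):
        lib = AssayLibrary([_prec("AADDEFGHK", "P1"), _prec("CCDDEFGHK", "P1")])
        assert census(protein_min_peptides(lib, 2)).n_proteins == 1

    def test_empty_library(self):
        assert protein_min_peptides(AssayLibrary(), 2).precursors == []


class TestCascadeOnFixture:
    def test_final_census_matches_construction_oracle(self, cascade_fixture):
        fx = cascade_fixture
        training, _ = pipeline.prepare_training_data(
            fx.library, fx.chromatograms, fx.truth.irt_standards
        )
        final, report = run_cascade(fx.library, training, fx.annotations)
        assert census(final) == fx.expected_census

    def test_postconditions_hold_globally(self, cascade_fixture):
        fx = cascade_fixture
        training, _ = pipeline.prepare_training_data(
            fx.library, fx.chromatograms, fx.truth.irt_standards
        )
        final, _ = run_cascade(fx.library, training, fx.annotations)
        seqs = [p.peptide.sequence for p in final.precursors]
        assert len(seqs) == len(set(seqs))  # no repeated peptides
        pep_per_protein = {}
        for p in final.precursors:
            assert not p.peptide.has_disallowed_modification()
            assert len(p.peptide.protein_ids) == 1
            assert len(p.transitions) >= 4
            assert p.peptide.missed_cleavages == 0
            pep_per_protein.setdefault(p.peptide.protein_ids[0], set()).add(
                p.peptide.sequence
            )
        assert all(len(v) >= 2 for v in pep_per_protein.values())

    def test_report_censuses_non_increasing(self, cascade_fixture):
        fx = cascade_fixture
        training, _ = pipeline.prepare_training_data(
            fx.library, fx.chromatograms, fx.truth.irt_standards
        )
        _, report = run_cascade(fx.library, training, fx.annotations)
        df = report.to_frame()
        for col in ("proteins", "peptides", "precursors", "transitions"):
            assert (np.diff(df[col]) <= 0).all()

    def test_no_violations_nothing_removed(self):
        from diaforge.simulate import make_cascade_fixture

        fx = make_cascade_fixture(seed=21, violations=False)
        training, _ = pipeline.prepare_training_data(
            fx.library, fx.chromatograms, fx.truth.irt_standards
        )
        final, _ = run_cascade(fx.library, training, fx.annotations)
        assert census(final) == census(fx.library)
        assert census(final) == fx.expected_census

    def test_provenance_lists_all_steps(self, cascade_fixture):
        fx = cascade_fixture
        training, _ = pipeline.prepare_training_data(
            fx.library, fx.chromatograms, fx.truth.irt_standards
        )
        final, _ = run_cascade(fx.library, training, fx.annotations)
        assert [s for s in final.provenance if s.startswith("step")] == [
            f"step{i}" for i in range(1, 8)
        ]


class TestCurationSettings:
    def test_positive_parameters_enforced(self):
        with pytest.raises(ValidationError):
            CurationSettings(rt_window=-1.0)
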
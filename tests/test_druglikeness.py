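import math

import pytest
from hypothesis import given, settings, strategies as st

from spheropv import druglikeness as dl
from spheropv.errors import MissingDataError


class TestRo5:
    @pytest.mark.parametrize(
        "mw, logp, hbd, hba, expected_violations",
        [
            (300, 2, 2, 5, 0),
            (543.5, 1.3, 6, 12, 3),   # doxorubicin-like: mw, hbd, hba breached
            (500, 5, 5, 10, 0),       # exact thresholds are not violations
            (501, 5.1, 6, 11, 4),
        ],
    )
    def test_violation_count(self, make_record, mw, logp, hbd, hba, expected_violations):
        rec = make_record(mw=mw, logp=logp, hbd_count=hbd, hba_count=hba)
        n, ok, details = dl.evaluate_ro5(rec, max_violations=0)
        assert n == expected_violations
        assert ok is (n == 0)
        assert len(details) == n

    def test_doxorubicin_like_fails_even_with_one_allowed(self, make_record):
        rec = make_record(mw=543.5, logp=1.3, hbd_count=6, hba_count=12)
        _, ok, _ = dl.evaluate_ro5(rec, max_violations=1)
        assert not ok

    @given(
        mw=st.floats(100, 1200), logp=st.floats(-5, 10),
        hbd=st.integers(0, 12), hba=st.integers(0, 20),
        allow=st.integers(0, 4), tighter=st.integers(0, 4),
    )
    @settings(deadline=None, max_examples=60)
    def test_tightening_allowance_is_monotone(self, mw, logp, hbd, hba, allow, tighter):
        from spheropv.chem_data import DrugDescriptorRecord

        rec = DrugDescriptorRecord(
            drug_id="h", mw=mw, logp=logp, hbd_count=hbd, hba_count=hba
        )
        _, ok_a, _ = dl.evaluate_ro5(rec, max_violations=max(allow, tighter))
        _, ok_b, _ = dl.evaluate_ro5(rec, max_violations=min(allow, tighter))
        assert ok_a or not ok_b  # pass can only flip to fail when tightening

    def test_missing_descriptor(self, make_record):
        rec = make_record()
        rec.logp = None
        with pytest.raises(MissingDataError, match="logp"):
            dl.evaluate_ro5(rec)


class TestGhoseVeber:
    def test_ghose_interior_and_bounds(self, make_record):
        ok, _ = dl.evaluate_ghose(make_record(mw=300, logp=2.0, refractivity=80, atom_count=30))
        assert ok
        ok, details = dl.evaluate_ghose(make_record(mw=150, logp=2.0, refractivity=80, atom_count=30))
        assert not ok and "mw" in details[0] and "below 160" in details[0]
        ok, _ = dl.evaluate_ghose(make_record(mw=480, logp=5.6, refractivity=130, atom_count=70))
        assert ok  # inclusive upper bounds

    @pytest.mark.parametrize(
        "rotb, psa, expected",
        [(5, 90, True), (11, 90, False), (10, 140, True), (5, 140.5, False)],
    )
    def test_veber(self, make_record, rotb, psa, expected):
        ok, _ = dl.evaluate_veber(make_record(rotatable_bonds=rotb, psa=psa))
        assert ok is expected


def _argmax(descriptor):
    """Locate the maximizer of one desirability curve by dense grid + refinement."""
    import numpy as np

    lo, hi = {"MW": (0, 1000), "ALOGP": (-5, 10), "HBA": (0, 15), "HBD": (0, 10),
              "PSA": (0, 300), "ROTB": (0, 20), "AROM": (0, 8), "ALERTS": (0, 8)}[descriptor]
    xs = np.linspace(lo, hi, 20001)
    ys = [dl.desirability(descriptor, x) for x in xs]
    i = int(np.argmax(ys))
    # golden-section refinement around the grid maximum
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda x: -dl.desirability(descriptor, x),
        bounds=(xs[max(i - 1, 0)], xs[min(i + 1, len(xs) - 1)]),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


class TestQed:
    def test_qed_is_one_at_joint_desirability_maximum(self, make_record):
        """At each descriptor's desirability argmax the geometric mean is 1."""
        argmaxes = {name: _argmax(name) for name in dl.QED_PARAMETERS}
        rec = make_record(
            mw=argmaxes["MW"],
            logp=argmaxes["ALOGP"],
            hba_count=round(argmaxes["HBA"]),
            hbd_count=round(argmaxes["HBD"]),
            psa=argmaxes["PSA"],
            rotatable_bonds=round(argmaxes["ROTB"]),
            aromatic_ring_count=round(argmaxes["AROM"]),
            alerts_count=round(argmaxes["ALERTS"]),
        )
        # integer descriptors cannot sit exactly at a fractional argmax, so
        # evaluate the continuous product directly for the exactness check
        q_cont = math.exp(
            sum(math.log(dl.desirability(n, argmaxes[n])) for n in dl.QED_PARAMETERS) / 8
        )
        assert q_cont == pytest.approx(1.0, abs=1e-6)
        assert dl.compute_qed_unweighted(rec) == pytest.approx(1.0, abs=0.05)

    def test_qed_matches_rdkit_unweighted_oracle(self):
        """Unweighted QED agrees with RDKit's equal-weight QED to 1e-9."""
        pytest.importorskip("rdkit")
        from rdkit import Chem
        from rdkit.Chem import QED

        from spheropv.chem_data import compute_descriptors_from_structure

        smiles = [
            "CC(=O)Oc1ccccc1C(=O)O",                   # aspirin
            "Cn1cnc2c1c(=O)n(C)c(=O)n2C",              # caffeine
            "CC(C)Cc1ccc(cc1)C(C)C(=O)O",              # ibuprofen
            "N=C(CCSCc1csc(N=C(N)N)n1)NS(N)(=O)=O",    # famotidine
        ]
        for smi in smiles:
            rec = compute_descriptors_from_structure(smi)
            mine = dl.compute_qed_unweighted(rec)
            ref = QED.qed(Chem.MolFromSmiles(smi), w=QED.WEIGHT_NONE)
            assert mine == pytest.approx(ref, abs=1e-9), smi

    def test_qed_strictly_increases_with_single_desirability(self, make_record):
        # ALERTS desirability decreases monotonically: fewer alerts, higher QED
        q = [dl.compute_qed_unweighted(make_record(alerts_count=k)) for k in (0, 1, 2, 3)]
        assert all(a > b for a, b in zip(q, q[1:]))
        assert all(0.0 <= v <= 1.0 for v in q)

    def test_missing_descriptor_refused(self, make_record):
        rec = make_record()
        rec.aromatic_ring_count = None
        with pytest.raises(MissingDataError, match="aromatic_ring_count"):
            dl.compute_qed_unweighted(rec)  # no silent subset QED


class TestProfiles:
    def test_fully_druglike_record_passes_all(self, make_record):
        prof = dl.profile_drug(make_record())
        assert prof.ro5_pass and prof.ghose_pass and prof.veber_pass and prof.qed_pass

    def test_single_rule_failure_is_isolated(self, make_record):
        prof = dl.profile_drug(make_record(rotatable_bonds=12, mw=300))
        assert prof.veber_pass is False
        assert prof.ro5_pass and prof.ghose_pass
        assert "veber" in prof.per_rule_details

    def test_missing_field_marks_rule_not_evaluable(self, make_record):
        rec = make_record()
        rec.refractivity = None
        prof = dl.profile_drug(rec)
        assert prof.ghose_pass is None
        assert "not evaluable" in prof.per_rule_details["ghose"][0]
        assert prof.ro5_pass is not None and prof.veber_pass is not None

    def test_profile_table_stable_under_reordering(self, synthetic_records):
        fwd = dl.profile_table(synthetic_records)
        rev = dl.profile_table(list(reversed(synthetic_records)))
        merged = fwd.set_index("drug_id").sort_index()
        assert merged.equals(rev.set_index("drug_id").sort_index())

    def test_reevaluation_is_bit_identical(self, make_record):
        rec = make_record(mw=431.7, logp=3.3)
        a = dl.compute_qed_unweighted(rec)
        b = dl.compute_qed_unweighted(rec)
        assert a == b
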
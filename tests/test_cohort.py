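"""Derived indices, outcome labels, flow accounting and CSV round-trips."""

import math

import pytest
from hypothesis import given, strategies as st

from pcosmet.cohort import (
    Cohort,
    CohortParseError,
    DomainError,
    PatientRecord,
    PatientVisit,
    compute_bmi,
    compute_derived,
    compute_fai,
    compute_homa_ir,
    flow_report,
    label_outcomes,
    rate,
    read_cohort_csv,
    write_cohort_csv,
)


def make_visit(name="m0", **overrides):
    values = dict(
        weight=87.2, glucose=90.0, insulin=18.0, tg=110.0, tc=185.0,
        ldl=120.0, hdl=43.0, waist=95.0, hip=105.0, t=0.60, shbg=34.7,
        dheas=270.0, a4=4.0, fg=12.0, lh=6.9, fsh=5.5, menses6=2.0,
        afc=40.0, pcom=True,
    )
    values.update(overrides)
    return PatientVisit(visit=name, **values)


def make_record(pid="P1", visits=("m0",), status=None, interval=None, height=1.63, **vo):
    vs = {}
    prev = None
    for name in visits:
        prev = make_visit(name, **vo.get(name, {}))
        vs[name] = prev
    if status is None:
        status = "completed" if "m12" in visits else "lost_followup"
    if interval is None:
        interval = "none" if status == "completed" else (
            "m0_m6" if "m6" not in visits else "m6_m12"
        )
    return PatientRecord(patient_id=pid, age=28.0, height=height, visits=vs,
                         status=status, dropout_interval=interval)


# ---------------------------------------------------------------------------
# Index formulas
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "t, shbg, expected",
    [(0.60, 34.7, 6.00), (0.0, 25.0, 0.0), (0.70, 23.1, 10.5152)],
)
def test_fai_values(t, shbg, expected):
    assert compute_fai(t, shbg) == pytest.approx(expected, abs=5e-4)


@pytest.mark.parametrize(
    "glucose, insulin, expected",
    [(90.0, 18.0, 3.99672), (123.0, 0.0, 0.0), (91.64, 21.03, 4.7546)],
)
def test_homa_values(glucose, insulin, expected):
    assert compute_homa_ir(glucose, insulin) == pytest.approx(expected, abs=5e-4)


def test_index_domain_errors():
    with pytest.raises(DomainError):
        compute_fai(0.6, 0.0)
    with pytest.raises(DomainError):
        compute_fai(-0.1, 20.0)
    with pytest.raises(DomainError):
        compute_homa_ir(-1.0, 10.0)
    with pytest.raises(DomainError):
        compute_bmi(70.0, 0.0)


@given(
    t=st.floats(0.01, 5.0),
    shbg=st.floats(1.0, 100.0),
    glucose=st.floats(40.0, 200.0),
    insulin=st.floats(0.5, 80.0),
    k=st.floats(1.1, 10.0),
)
def test_indices_homogeneous_degree_one(t, shbg, glucose, insulin, k):
    """Doubling the numerator variable doubles the index."""
    assert compute_fai(k * t, shbg) == pytest.approx(k * compute_fai(t, shbg), rel=1e-9)
    assert compute_homa_ir(glucose, k * insulin) == pytest.approx(
        k * compute_homa_ir(glucose, insulin), rel=1e-9
    )


def test_derived_panel_table_values():
    visit = make_visit(weight=87.2)
    panel = compute_derived(visit, height=1.63)
    assert panel.bmi == pytest.approx(32.82, abs=0.005)
    assert panel.whr == pytest.approx(95.0 / 105.0)
    assert panel.lh_fsh == pytest.approx(6.9 / 5.5)
    equal = compute_derived(make_visit(waist=100.0, hip=100.0), height=1.63)
    assert equal.whr == pytest.approx(1.0)


def test_derived_errors_name_field():
    with pytest.raises(DomainError, match="hip"):
        compute_derived(make_visit(hip=0.0), height=1.63)
    with pytest.raises(DomainError, match="FSH"):
        compute_derived(make_visit(fsh=0.0), height=1.63)


# ---------------------------------------------------------------------------
# Outcome labels
# ---------------------------------------------------------------------------

def record_with_bmi(bmi0, bmi6=None, bmi12=None, fai0=13.0, height=1.63):
    visits = ["m0"]
    vo = {"m0": {"weight": bmi0 * height**2, "t": fai0 * 34.7 / 347.0}}
    if bmi6 is not None:
        visits.append("m6")
        vo["m6"] = {"weight": bmi6 * height**2}
    if bmi12 is not None:
        visits.append("m12")
        vo["m12"] = {"weight": bmi12 * height**2}
    return make_record(visits=tuple(visits), height=height, **vo)


def test_bmi_response_boundary():
    # height 1 makes weight and BMI coincide exactly, so the Δ >= 1 boundary
    # is hit without floating-point slack
    exactly_one = record_with_bmi(33.0, 32.0, height=1.0)
    assert label_outcomes(exactly_one).bmi_responder_m6 is True
    below = record_with_bmi(33.0, 32.25, height=1.0)
    assert label_outcomes(below).bmi_responder_m6 is False


def test_fai_ineligible_regardless_of_change():
    rec = record_with_bmi(32.8, 30.0, fai0=5.9)
    labels = label_outcomes(rec)
    assert labels.fai_eligible is False
    assert labels.fai_responder_m6 is None


def test_missing_visit_gives_undefined_label():
    labels = label_outcomes(record_with_bmi(32.8))
    assert labels.bmi_responder_m6 is None
    assert labels.bmi_responder_m12 is None


def test_m12_label_is_further_change_from_m6():
    # total drop 1.6 but second-interval drop only 0.4: responder at m6, not at m12
    labels = label_outcomes(record_with_bmi(32.8, 31.6, 31.2))
    assert labels.bmi_responder_m6 is True
    assert labels.bmi_responder_m12 is False
    labels2 = label_outcomes(record_with_bmi(32.8, 31.6, 30.5))
    assert labels2.bmi_responder_m12 is True


@given(drop=st.floats(0.0, 10.0), extra=st.floats(0.0, 5.0))
def test_bigger_bmi_drop_never_flips_responder_off(drop, extra):
    base = label_outcomes(record_with_bmi(35.0, 35.0 - drop)).bmi_responder_m6
    more = label_outcomes(record_with_bmi(35.0, 35.0 - drop - extra)).bmi_responder_m6
    assert more or not base


# ---------------------------------------------------------------------------
# Flow accounting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "num, den, pct",
    [(54, 103, 52.4), (0, 17, 0.0), (9, 108, 8.3), (45, 89, 50.6), (82, 108, 75.9)],
)
def test_rate_percent(num, den, pct):
    assert rate(num, den).percent == pct


@given(num=st.integers(0, 500), den=st.integers(1, 500))
def test_rate_recomputes_from_own_pair(num, den):
    if num > den:
        num = den
    r = rate(num, den)
    assert rate(r.numerator, r.denominator).percent == r.percent
    assert abs(r.percent - 100 * num / den) <= 0.05 + 1e-12


def test_flow_report_requires_nonempty():
    with pytest.raises(DomainError):
        flow_report(Cohort(records=[]))


def test_flow_interval_balance(reference_cohort):
    report = flow_report(reference_cohort)
    first = sum(report.dropouts["m0_m6"].values())
    assert report.enrolled - first - report.pregnancies["m0_m6"] == report.completed_m6


# ---------------------------------------------------------------------------
# Record invariants and CSV round trip
# ---------------------------------------------------------------------------

def test_record_invariants():
    with pytest.raises(ValueError, match="m0"):
        PatientRecord(patient_id="X", age=28.0, height=1.6,
                      visits={"m6": make_visit("m6")}, status="lost_followup",
                      dropout_interval="m0_m6")
    with pytest.raises(ValueError, match="completed"):
        make_record(visits=("m0", "m6"), status="completed", interval="none")
    with pytest.raises(ValueError, match="menses6"):
        make_visit(menses6=7.0)
    with pytest.raises(ValueError, match="Ferriman"):
        make_visit(fg=40.0)


def test_csv_round_trip(tmp_path):
    cohort = Cohort(
        records=[
            make_record("A", ("m0", "m6", "m12")),
            make_record("B", ("m0", "m6"), status="dropout_no_benefit", interval="m6_m12"),
            make_record("C", ("m0",), status="pregnant", interval="m0_m6"),
        ]
    )
    path = tmp_path / "cohort.csv"
    write_cohort_csv(cohort, path)
    back = read_cohort_csv(path)
    assert back.ids() == ["A", "B", "C"]
    for orig, re in zip(cohort, back):
        assert orig.status == re.status
        assert set(orig.visits) == set(re.visits)
        for v in orig.visits:
            assert orig.visits[v].weight == pytest.approx(re.visits[v].weight)
            assert orig.visits[v].shbg == pytest.approx(re.visits[v].shbg)


def test_csv_errors(tmp_path):
    empty = tmp_path / "empty.csv"
    empty.write_text("")
    with pytest.raises(CohortParseError):
        read_cohort_csv(empty)

    cohort = Cohort(records=[make_record("A", ("m0", "m6", "m12"))])
    path = tmp_path / "ok.csv"
    write_cohort_csv(cohort, path)
    lines = path.read_text().splitlines()

    # visit m6 without m0
    bad = tmp_path / "orphan.csv"
    bad.write_text("\n".join([lines[0], lines[2]]))
    with pytest.raises(CohortParseError, match="m0"):
        read_cohort_csv(bad)

    # duplicate patient-visit with line number
    dup = tmp_path / "dup.csv"
    dup.write_text("\n".join([lines[0], lines[1], lines[1]]))
    with pytest.raises(CohortParseError, match="line 3"):
        read_cohort_csv(dup)

    # missing mandatory column
    cols = lines[0].split(",")
    chopped = tmp_path / "chopped.csv"
    chopped.write_text(
        "\n".join(",".join(row.split(",")[1:]) for row in lines)
    )
    with pytest.raises(CohortParseError, match="patient_id"):
        read_cohort_csv(chopped)

    # non-numeric cell
    broken = tmp_path / "nonnum.csv"
    row = lines[1].split(",")
    row[4] = "heavy"
    broken.write_text("\n".join([lines[0], ",".join(row)]))
    with pytest.raises(CohortParseError, match="line 2"):
        read_cohort_csv(broken)
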
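"""The three region rules, their orchestration, and an independent
brute-force oracle."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigpepvar import (
    AMINO_ACIDS,
    AnnotationError,
    ClassificationConfig,
    Mechanism,
    MissenseVariant,
    Region,
    SigPepVarError,
    SignalPeptide,
    classify_batch,
    classify_c,
    classify_h,
    classify_n,
    classify_pair,
    classify_variant,
    position_frequency_table,
)

# ---------------------------------------------------------------------------
# Independent brute-force oracle: scales transcribed separately and rules
# re-derived from their definitions, no sigpepvar arithmetic reused.
# ---------------------------------------------------------------------------

ORACLE_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
ORACLE_BOMAN = {
    "L": -4.92, "I": -4.92, "V": -4.04, "F": -2.98, "M": -2.35, "W": -2.33,
    "A": -1.81, "C": -1.28, "G": -0.94, "Y": 0.14, "P": 0.0, "T": 2.57,
    "S": 3.4, "H": 4.66, "Q": 5.54, "K": 5.55, "N": 6.64, "E": 6.81,
    "D": 8.72, "R": 14.92,
}


def oracle_classify(sp, pos, mut, freqs, cutoff=20.0, rarity=0.025):
    """Re-derive the rule outcome from scratch for one substitution."""
    wt = sp.sequence[pos - 1]
    if pos <= sp.n_end:
        region = "N"
    elif pos <= sp.h_end:
        region = "H"
    elif pos <= sp.sp_len:
        region = "C"
    elif pos == sp.sp_len + 1:
        region = "PLUS1"
    else:
        region = "OUTSIDE"
    if region == "H":
        wt_index = sum(ORACLE_BOMAN[r] for r in sp.sequence) / len(sp.sequence)
        mut_seq = sp.sequence[: pos - 1] + mut + sp.sequence[pos:]
        mut_index = sum(ORACLE_BOMAN[r] for r in mut_seq) / len(mut_seq)
        decrease = ORACLE_KD[mut] - ORACLE_KD[wt] < 0
        boman_up = (mut_index - wt_index) * 100 >= cutoff
        return ("RAPP_MRNA_DECAY" if decrease and boman_up else "NONE")
    if region in ("C", "PLUS1"):
        rel = pos - sp.sp_len - 1 if pos <= sp.sp_len else 1
        if rel in (-3, -1, 1) and freqs.get(rel, {}).get(mut, 0.0) < rarity:
            return "PROCESSING_FAILURE"
        return "NONE"
    if region == "N":
        return (
            "TRANSLOCATION_DEFECT"
            if mut in "DE" and wt not in "DE"
            else "NONE"
        )
    return "NONE"


def oracle_freqs(peptides):
    """Hand-rolled cleavage-anchored frequency table."""
    out = {}
    for rel in (-6, -5, -4, -3, -2, -1, 1):
        counts = {}
        for sp in peptides:
            pos = sp.sp_len + 1 + rel if rel < 0 else sp.sp_len + rel
            if 1 <= pos <= len(sp.sequence):
                res = sp.sequence[pos - 1]
                counts[res] = counts.get(res, 0) + 1
        total = sum(counts.values())
        out[rel] = {r: c / total for r, c in counts.items()}
    return out


# ---------------------------------------------------------------------------
# H-rule
# ---------------------------------------------------------------------------

AGA_SP = SignalPeptide("AGA", "AGA", "MARKSNLPVLLVPFLLCQALVRCS", 4, 16, 23)


def test_h_rule_flags_hydrophobicity_loss_with_boman_jump():
    v = MissenseVariant("rs386833429", "AGA", 15, "L", "R")
    res = classify_h(AGA_SP, v)
    assert res.is_ppv and res.mechanism is Mechanism.RAPP_MRNA_DECAY
    assert res.scores.delta_kd < 0 and res.scores.scaled_boman_change >= 20


def test_h_rule_ignores_hydrophobicity_increase():
    # R->H raises hydropathy, so the decay rule cannot fire
    ins = SignalPeptide("INS", "INS", "MALWMRLLPLLALLALWGPDPAAAF", 5, 15, 24)
    v = MissenseVariant("rs121908259", "INS", 6, "R", "H")
    res = classify_variant(ins, v, position_frequency_table([ins, AGA_SP]))
    assert not res.is_ppv and res.mechanism is Mechanism.NONE


def test_h_rule_requires_boman_cutoff(table1):
    """A hydrophobicity decrease whose Boman change stays under the cutoff
    (SERPINE1 A15T) is not flagged."""
    row = table1[table1.variant_id == "rs6092"].iloc[0]
    res = classify_pair(row.wt_seq, row.mut_seq)
    assert res.scores.delta_kd < 0
    assert 0 < res.scores.scaled_boman_change < 20
    assert not res.is_ppv


def test_h_rule_rejects_non_h_variant(toy_peptide):
    v = MissenseVariant("v", "TOY1", 2, "K", "R")
    with pytest.raises(AnnotationError):
        classify_h(toy_peptide, v)


# ---------------------------------------------------------------------------
# C-rule
# ---------------------------------------------------------------------------


def c_fixture():
    """Collection where the −1 position is A in 6/8 peptides and C in 2/8,
    so A and C are common there while Y is never observed."""
    peptides = [
        SignalPeptide(
            f"P{i}", f"G{i}",
            "MKR" + "L" * 12 + "SGA" + ("A" if i < 6 else "C") + "S",
            3, 15, 19,
        )
        for i in range(8)
    ]
    return peptides, position_frequency_table(peptides)


def test_c_rule_flags_rare_incoming_residue():
    peptides, table = c_fixture()
    v = MissenseVariant("v", "P0", 19, "A", "Y")  # -1 position, Y unseen
    res = classify_c(peptides[0], v, table)
    assert res.is_ppv and res.mechanism is Mechanism.PROCESSING_FAILURE
    assert res.mut_position_frequency == 0.0


def test_c_rule_passes_common_incoming_residue():
    peptides, table = c_fixture()
    v = MissenseVariant("v", "P0", 19, "A", "C")  # C holds 25% of -1
    res = classify_c(peptides[0], v, table)
    assert not res.is_ppv
    assert res.mut_position_frequency == pytest.approx(0.25)


def test_c_rule_skips_positions_outside_default_set():
    peptides, table = c_fixture()
    v = MissenseVariant("v", "P0", 16, "S", "Y")  # cleavage-relative -4
    res = classify_c(peptides[0], v, table)
    assert not res.is_ppv and res.mut_position_frequency is None


def test_c_rule_requires_frequency_table():
    peptides, _ = c_fixture()
    v = MissenseVariant("v", "P0", 19, "A", "Y")
    with pytest.raises(SigPepVarError):
        classify_c(peptides[0], v, None)


def test_c_rule_evaluates_plus_one():
    peptides, table = c_fixture()
    v = MissenseVariant("v", "P0", 20, "S", "W")  # +1 position, W unseen
    res = classify_c(peptides[0], v, table)
    assert res.mapped.region is Region.PLUS1
    assert res.is_ppv and res.mechanism is Mechanism.PROCESSING_FAILURE


def test_c_rule_all_positions_option():
    peptides, table = c_fixture()
    cfg = ClassificationConfig(c_all_positions=True)
    v = MissenseVariant("v", "P0", 16, "S", "Y")  # -4, Y unseen there
    res = classify_c(peptides[0], v, table, cfg)
    assert res.is_ppv


# ---------------------------------------------------------------------------
# N-rule
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "wt, mut, flagged",
    [("A", "D", True), ("K", "E", True), ("D", "E", False), ("K", "M", False)],
)
def test_n_rule(wt, mut, flagged):
    seq = "M" + wt + "R" + "L" * 12 + "SAHA" + "S"
    sp = SignalPeptide("P", "G", seq, 3, 15, 19)
    v = MissenseVariant("v", "P", 2, wt, mut)
    res = classify_n(sp, v)
    assert res.is_ppv is flagged
    assert res.mechanism is (
        Mechanism.TRANSLOCATION_DEFECT if flagged else Mechanism.NONE
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def test_dispatch_is_deterministic_and_single_mechanism(toy_peptide):
    table = position_frequency_table([toy_peptide])
    v = MissenseVariant("v", "TOY1", 5, "L", "R")
    r1 = classify_variant(toy_peptide, v, table)
    r2 = classify_variant(toy_peptide, v, table)
    assert r1 == r2
    assert r1.mechanism in set(Mechanism)


def test_outside_variant_passes_through(toy_peptide):
    table = position_frequency_table([toy_peptide])
    v = MissenseVariant("v", "TOY1", 40, "A", "R")
    res = classify_variant(toy_peptide, v, table)
    assert res.mapped.region is Region.OUTSIDE
    assert not res.is_ppv and res.mechanism is Mechanism.NONE


def test_exhaustive_scan_matches_bruteforce_oracle(toy_peptide, toy_collection):
    """All 19 substitutions at every position of a toy peptide agree with
    the independently coded rule oracle."""
    peptides = [toy_peptide] + toy_collection
    table = position_frequency_table(peptides)
    freqs = oracle_freqs(peptides)
    n_checked = 0
    for pos in range(1, toy_peptide.sp_len + 2):
        wt = toy_peptide.residue(pos)
        for mut in AMINO_ACIDS:
            if mut == wt:
                continue
            v = MissenseVariant(f"s{pos}{mut}", "TOY1", pos, wt, mut)
            got = classify_variant(toy_peptide, v, table).mechanism.value
            expected = oracle_classify(toy_peptide, pos, mut, freqs)
            assert got == expected, (pos, wt, mut)
            n_checked += 1
    assert n_checked == 19 * (toy_peptide.sp_len + 1)


@settings(deadline=None, derandomize=True)
@given(data=st.data())
def test_h_rule_monotone_in_incoming_hydropathy(data):
    """Replacing the incoming residue by a strictly more hydrophobic one
    never turns a non-PPV into a PPV via the hydrophobicity criterion."""
    sp = AGA_SP
    pos = data.draw(st.integers(min_value=sp.n_end + 1, max_value=sp.h_end))
    wt = sp.residue(pos)
    muts = [r for r in AMINO_ACIDS if r != wt]
    mut = data.draw(st.sampled_from(muts))
    from sigpepvar import KYTE_DOOLITTLE

    higher = [r for r in muts if KYTE_DOOLITTLE[r] > KYTE_DOOLITTLE[mut]]
    if not higher:
        return
    mut2 = data.draw(st.sampled_from(higher))
    res = classify_h(sp, MissenseVariant("a", "AGA", pos, wt, mut))
    res2 = classify_h(sp, MissenseVariant("b", "AGA", pos, wt, mut2))
    if not res.is_ppv and res.scores.delta_kd >= 0:
        assert not res2.is_ppv


def test_batch_empty_variants(toy_collection):
    batch = classify_batch(toy_collection, [])
    assert batch.results == [] and batch.summary.n_ppv == 0
    assert batch.summary.n_variants == 0


def test_batch_reports_unresolvable_protein(toy_collection):
    v = MissenseVariant("vX", "NOPE", 5, "L", "R")
    batch = classify_batch(toy_collection, [v])
    assert batch.results == []
    assert batch.rejects and batch.rejects[0][0] == "vX"


def test_batch_reports_reference_mismatch(toy_collection):
    v = MissenseVariant("vY", "P1", 5, "A", "R")  # stored residue is L
    batch = classify_batch(toy_collection, [v])
    assert batch.rejects and "mismatch" in batch.rejects[0][1]


def test_table1_pairs_reproduce_published_predictions(table1):
    """Every literature pair classifies to its experimentally observed
    decay outcome: 8 decay predictions, 7 non-decay."""
    decay, no_decay = 0, 0
    for _, row in table1.iterrows():
        res = classify_pair(row.wt_seq, row.mut_seq, variant_id=row.variant_id)
        predicted = "decay" if res.is_ppv else "no_decay"
        assert predicted == row.expected, row.variant_id
        if res.is_ppv:
            assert res.mechanism is Mechanism.RAPP_MRNA_DECAY
            decay += 1
        else:
            no_decay += 1
    assert (decay, no_decay) == (8, 7)
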
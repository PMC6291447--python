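"""Decision tree, cross-structure aggregation, and the full pipeline."""

import itertools
import json
import random

import pytest

from sasdiag import diagnosis, fixtures
from sasdiag.diagnosis import (
    AnnotationFlags,
    LABELS,
    NON_PATHOGENIC,
    aggregate_structures,
    build_flags,
    diagnose,
    run_pipeline,
)
from sasdiag.model import Variant
from sasdiag.residue_annotation import ResidueAnnotation


def make_flags(ddg_high=False, active=False, interface=False, buried=False,
               agg=False, switch=False, ddg=None, sid="s1"):
    if ddg is None:
        ddg = 3.0 if ddg_high else 0.5
    return AnnotationFlags(ddg=ddg, ddg_high=ddg_high, active_site=active,
                           interface=interface, buried=buried,
                           high_aggregability=agg, high_switchability=switch,
                           structure_id=sid)


# --- independent truth-table oracle ----------------------------------------
# Hand-coded row by row: each rule is a complete predicate over the six
# flags, ordered as the decision table reads, left to right and top to
# bottom. A destabilising variant with no positional/sequence flag is a
# folding disruptor (destabilisation alone prevents folding).

ORACLE_ROWS = [
    ("Disrupt protein function",
     lambda d, a, i, b, g, s: d and a),
    ("Disrupt protein interface",
     lambda d, a, i, b, g, s: d and not a and i),
    ("Disrupt protein folding",
     lambda d, a, i, b, g, s: d and not a and not i and b),
    ("Disrupt protein structure",
     lambda d, a, i, b, g, s: d and not a and not i and not b and (g or s)),
    ("Potential disruption protein function",
     lambda d, a, i, b, g, s: not d and a),
    ("Potential disruption protein interface",
     lambda d, a, i, b, g, s: not d and not a and i),
    ("Potential disruption protein folding",
     lambda d, a, i, b, g, s: not d and not a and not i and b),
    ("Potential disruption protein structure",
     lambda d, a, i, b, g, s: not d and not a and not i and not b and (g or s)),
    ("Likely non pathogenic mutation",
     lambda d, a, i, b, g, s: not d and not a and not i and not b and not g and not s),
    ("Disrupt protein folding",  # destabilisation-only fall-through
     lambda d, a, i, b, g, s: d and not a and not i and not b and not g and not s),
]


def oracle_label(d, a, i, b, g, s):
    hits = [label for label, pred in ORACLE_ROWS if pred(d, a, i, b, g, s)]
    assert len(hits) == 1, f"oracle rows must partition the space, got {hits}"
    return hits[0]


ALL_COMBOS = list(itertools.product([False, True], repeat=6))


def test_decision_tree_matches_oracle_on_all_64_combinations():
    for d, a, i, b, g, s in ALL_COMBOS:
        flags = make_flags(ddg_high=d, active=a, interface=i, buried=b, agg=g, switch=s)
        assert diagnose(flags).label == oracle_label(d, a, i, b, g, s), (d, a, i, b, g, s)


def test_exactly_one_rule_fires_and_labels_are_known():
    seen = set()
    for combo in ALL_COMBOS:
        result = diagnose(make_flags(*combo[0:1], *combo[1:]))
        assert result.label in LABELS
        assert 1 <= result.fired_rule <= 9
        seen.add(result.label)
    assert seen == set(LABELS)  # every label reachable


def test_left_to_right_precedence():
    both = make_flags(ddg_high=True, active=True, interface=True)
    assert diagnose(both).label == "Disrupt protein function"
    int_buried = make_flags(ddg_high=True, interface=True, buried=True)
    assert diagnose(int_buried).label == "Disrupt protein interface"


def test_category_is_a_pure_function_of_label():
    expected = {
        "function": "Active site + Binding",
        "interface": "Protein-protein interaction",
        "folding": "Folding",
        "structure": "Folding",
    }
    label_to_category: dict[str, set[str]] = {}
    for combo in ALL_COMBOS:
        result = diagnose(make_flags(*combo))
        label_to_category.setdefault(result.label, set()).add(result.category)
    for label, cats in label_to_category.items():
        assert len(cats) == 1, f"{label} maps to several categories"
        category = next(iter(cats))
        if label == NON_PATHOGENIC:
            assert category == "None"
        else:
            assert category == expected[label.split()[-1]]
    # only the non-pathogenic label carries category None
    with_none = {l for l, c in label_to_category.items() if c == {"None"}}
    assert with_none == {NON_PATHOGENIC}


# --- flag assembly ----------------------------------------------------------

def _annotation(exposure=80.0, exposed=True, interface=False, binding=False,
                catalytic=False):
    return ResidueAnnotation(("A", 1, ""), "A", exposure, exposed, interface,
                             False, binding, catalytic, 1.0)


def test_active_site_is_binding_or_catalytic():
    v = Variant("A", 1, "V")
    assert build_flags(v, _annotation(binding=True), "s").active_site
    assert build_flags(v, _annotation(catalytic=True), "s").active_site
    assert not build_flags(v, _annotation(), "s").active_site


def test_glycine_undefined_exposure_is_never_buried():
    v = Variant("G", 1, "A")
    ann = ResidueAnnotation(("A", 1, ""), "G", None, None, False, False,
                            False, False, 1.0)
    assert build_flags(v, ann, "s").buried is False


def test_unknown_ddg_is_not_high():
    flags = build_flags(Variant("A", 1, "V"), _annotation(), "s", ddg=None)
    assert flags.ddg is None and flags.ddg_high is False
    assert diagnose(flags).label.startswith(("Potential", "Likely"))


# --- aggregation ------------------------------------------------------------

def _random_flags(rng, sid):
    return make_flags(
        ddg_high=False,
        active=rng.random() < 0.3, interface=rng.random() < 0.3,
        buried=rng.random() < 0.3, agg=rng.random() < 0.2,
        switch=rng.random() < 0.2,
        ddg=round(rng.uniform(-2, 5), 3), sid=sid,
    )


BOOL_FLAGS = ("active_site", "interface", "buried",
              "high_aggregability", "high_switchability")


def test_aggregation_or_semantics_random_trials():
    rng = random.Random(0)
    for _ in range(1000):
        group = [_random_flags(rng, f"s{i}") for i in range(rng.randint(1, 4))]
        combined = aggregate_structures(group)
        for name in BOOL_FLAGS:
            assert getattr(combined, name) == any(getattr(f, name) for f in group)
        assert combined.ddg == max(f.ddg for f in group)
        # idempotent / commutative
        doubled = aggregate_structures(list(group) + list(group))
        shuffled = group[:]
        rng.shuffle(shuffled)
        for name in BOOL_FLAGS + ("ddg", "ddg_high"):
            assert getattr(doubled, name) == getattr(combined, name)
            assert getattr(aggregate_structures(shuffled), name) == getattr(combined, name)
        # monotone: adding a structure never clears a set flag
        extended = aggregate_structures(list(group) + [_random_flags(rng, "sx")])
        for name in BOOL_FLAGS:
            assert getattr(extended, name) >= getattr(combined, name)


def test_aggregated_ddg_high_recomputed_from_max():
    group = [make_flags(ddg=0.5, sid="a"), make_flags(ddg=3.1, sid="b")]
    combined = aggregate_structures(group)
    assert combined.ddg == 3.1 and combined.ddg_high is True
    assert dict(combined.provenance)["ddg_high"] == ()  # no single structure had it


def test_single_structure_aggregation_is_identity():
    only = make_flags(ddg_high=True, active=True, ddg=2.5, sid="solo")
    combined = aggregate_structures([only])
    for name in BOOL_FLAGS + ("ddg", "ddg_high"):
        assert getattr(combined, name) == getattr(only, name)


def test_empty_aggregation_rejected():
    with pytest.raises(ValueError):
        aggregate_structures([])


def test_provenance_names_contributing_structures():
    group = [make_flags(active=True, sid="holo"), make_flags(sid="apo")]
    prov = dict(aggregate_structures(group).provenance)
    assert prov["active_site"] == ("holo",)


# --- pipeline ---------------------------------------------------------------

def test_demo_pipeline_labels(demo, demo_result):
    got = {short: rep.aggregated.label for short, rep in demo_result.reports.items()}
    assert got == demo.expected_labels


def test_demo_per_structure_vs_aggregate(demo_result):
    """Ligand contact exists only in the holo crystal, yet aggregation keeps
    the active-site call."""
    rep = demo_result.reports["A10V"]
    assert rep.per_structure["demo_holo"][0].active_site is True
    assert rep.per_structure["demo_apo"][0].active_site is False
    assert rep.aggregated_flags.active_site is True
    assert dict(rep.aggregated_flags.provenance)["active_site"] == ("demo_holo",)


def test_pipeline_is_deterministic(demo_config):
    a = run_pipeline(demo_config).to_json()
    b = run_pipeline(demo_config).to_json()
    assert a == b


def test_unmapped_variant_reported_not_labelled(demo, demo_config):
    import dataclasses
    config = dataclasses.replace(
        demo_config,
        variants=[Variant("A", 5, "V"), Variant("A", 500, "V")],
        variant_table=None,
    )
    result = run_pipeline(config)
    assert result.unmapped == ["A500V"]
    assert "A500V" not in result.reports


def test_variant_without_ddg_gets_caveat_and_potential_tier(demo, demo_config):
    import dataclasses
    config = dataclasses.replace(
        demo_config, variants=[Variant("A", 10, "V")], variant_table=None, foldx={},
    )
    rep = run_pipeline(config).reports["A10V"]
    assert rep.caveats == ["stability-unknown"]
    assert rep.aggregated.label == "Potential disruption protein function"


def test_pipeline_writes_reports(demo_config, tmp_path):
    import dataclasses
    config = dataclasses.replace(demo_config, out_dir=tmp_path / "out")
    result = run_pipeline(config)
    report = json.loads((tmp_path / "out" / "report.json").read_text())
    assert set(report["variants"]) == set(result.reports)
    assert (tmp_path / "out" / "summary.tsv").exists()
    assert (tmp_path / "out" / "demo_holo.annotation.tsv").exists()


def test_demo_summary_counts(demo_result):
    assert demo_result.summary == {
        "Active site + Binding": 1, "Protein-protein interaction": 1,
        "Folding": 1, "None": 1,
    }
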
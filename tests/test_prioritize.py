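"""Filter cascade: stage rules, frequency exceptions, oracle equivalence."""

import numpy as np
import pytest

from kindredscope.io import AnnotatedVariant, FormatError
from kindredscope.prioritize import (
    ConfigError,
    EXCLUDED_CONSEQUENCES,
    FilterConfig,
    consensus_score,
    filter_consequence,
    filter_depth,
    maf_filter,
    run_cascade,
)


def make_variant(i=0, gene="LDLR", consequence="missense", depth=50, af=None,
                 calls=None, meta=0.5):
    return AnnotatedVariant(
        chrom="19", pos=1000 + i, variant_id=f"v{i}", gene=gene,
        consequence=consequence, depth=depth, ref_symbol="G", alt_symbol="A",
        af={"gnomad": af}, predictor_calls=calls or {},
        scores={"metasvm": meta},
    )


def brute_force_cascade(variants, config):
    """Independent re-statement of the four rules, applied per variant."""
    survivors = []
    for v in variants:
        if v.consequence in EXCLUDED_CONSEQUENCES:
            continue
        if v.depth is None or v.depth < config.min_depth:
            continue
        if v.gene not in config.gene_list:
            continue
        afs = [v.af[d] for d in config.databases if v.af.get(d) is not None]
        if afs and max(afs) >= config.maf_cutoff:
            calls = [c for c in v.predictor_calls.values()
                     if c is not None and c != "U"]
            dmg = sum(c in {"D", "H", "M"} for c in calls)
            if calls and dmg / len(calls) < 0.5:
                continue
            if not calls and not config.uncalled_is_damaging:
                continue
        survivors.append(v.key)
    return set(survivors)


class TestStages:
    def test_stopgain_retained_synonymous_removed(self):
        stop = make_variant(1, gene="MSR1", consequence="stopgain")
        syn = make_variant(2, consequence="synonymous")
        assert filter_consequence([stop, syn]) == [stop]

    def test_unknown_consequence_label_rejected(self):
        v = make_variant(1)
        v.consequence = None
        with pytest.raises(FormatError, match="consequence"):
            filter_consequence([v])

    @pytest.mark.parametrize("depth,kept", [(21, True), (20, True), (19, False)])
    def test_depth_boundary_inclusive(self, depth, kept):
        v = make_variant(1, depth=depth)
        assert (filter_depth([v], 20) == [v]) is kept

    def test_random_depths_match_oracle(self, rng):
        variants = [make_variant(i, depth=int(d))
                    for i, d in enumerate(rng.integers(0, 60, size=200))]
        got = {v.key for v in filter_depth(variants, 20)}
        expected = {v.key for v in variants if v.depth >= 20}
        assert got == expected


class TestMafRule:
    def test_common_but_damaging_is_exception(self, kindred1):
        variants, _, _ = kindred1
        lcat = next(v for v in variants if v.gene == "LCAT")
        cfg = FilterConfig(gene_list=frozenset({"LCAT"}))
        assert maf_filter(lcat, cfg, consensus_score(lcat)) == "exception"

    def test_rare_variant_kept(self, kindred1):
        variants, _, _ = kindred1
        ldlr = next(v for v in variants if v.gene == "LDLR")
        cfg = FilterConfig(gene_list=frozenset({"LDLR"}))
        assert maf_filter(ldlr, cfg) == "keep"

    def test_novel_all_missing_kept(self, kindred1):
        variants, _, _ = kindred1
        apob = next(v for v in variants if v.gene == "APOB")
        cfg = FilterConfig(gene_list=frozenset({"APOB"}))
        assert maf_filter(apob, cfg) == "keep"

    def test_common_benign_discarded(self):
        v = make_variant(1, af=0.12, calls={"sift": "T", "fathmm": "T"})
        cfg = FilterConfig(gene_list=frozenset({"LDLR"}))
        assert maf_filter(v, cfg) == "discard"

    def test_unscoreable_common_variant_configurable(self):
        v = make_variant(1, af=0.05, calls={})
        keep_cfg = FilterConfig(gene_list=frozenset({"LDLR"}))
        drop_cfg = FilterConfig(gene_list=frozenset({"LDLR"}),
                                uncalled_is_damaging=False)
        assert maf_filter(v, keep_cfg) == "exception"
        assert maf_filter(v, drop_cfg) == "discard"


class TestCascade:
    def test_worked_example_eight_candidates_two_exceptions(self, kindred1, gene_panel):
        variants, _, _ = kindred1
        candidates, trace, scores = run_cascade(variants, FilterConfig(gene_list=gene_panel))
        assert len(candidates) == 8
        assert trace.exception_flags == {"rs66514853", "rs4986970"}
        # the classic pathogenic receptor variant ranks first
        assert candidates[0].gene == "LDLR"

    def test_all_common_benign_input_empty_candidates_full_trace(self):
        variants = [make_variant(i, af=0.2, calls={"sift": "T"}) for i in range(5)]
        candidates, trace, _ = run_cascade(
            variants, FilterConfig(gene_list=frozenset({"LDLR"}))
        )
        assert candidates == []
        assert trace.stages["maf"] == (5, 0, [v.key for v in variants])

    def test_empty_gene_list_is_config_error(self):
        with pytest.raises(ConfigError):
            run_cascade([make_variant(1)], FilterConfig(gene_list=frozenset()))

    def _random_variants(self, rng, n=50):
        genes = ["LDLR", "APOB", "LCAT", "OFFPANEL"]
        consequences = ["missense", "synonymous", "utr", "stopgain", "intronic"]
        call_sets = [
            {"sift": "D", "fathmm": "D"},
            {"sift": "T", "fathmm": "T"},
            {"sift": "D", "fathmm": "T"},
            {},
        ]
        af_choices = [None, 0.001, 0.02, 0.2]
        out = []
        for i in range(n):
            out.append(
                make_variant(
                    i,
                    gene=genes[rng.integers(len(genes))],
                    consequence=consequences[rng.integers(len(consequences))],
                    depth=int(rng.integers(0, 60)),
                    af=af_choices[rng.integers(len(af_choices))],
                    calls=dict(call_sets[rng.integers(len(call_sets))]),
                )
            )
        return out

    def test_survivors_equal_brute_force_oracle(self, rng):
        cfg = FilterConfig(gene_list=frozenset({"LDLR", "APOB", "LCAT"}))
        variants = self._random_variants(rng)
        candidates, trace, _ = run_cascade(variants, cfg)
        assert {v.key for v in candidates} == brute_force_cascade(variants, cfg)

    def test_trace_conserves_counts(self, kindred1, gene_panel):
        variants, _, _ = kindred1
        _, trace, _ = run_cascade(variants, FilterConfig(gene_list=gene_panel))
        for n_in, n_out, removed in trace.stages.values():
            assert n_in == n_out + len(removed)
        names = list(trace.stages)
        for a, b in zip(names, names[1:]):
            assert trace.stages[a][1] == trace.stages[b][0]

    def test_membership_order_insensitive(self, rng):
        cfg = FilterConfig(gene_list=frozenset({"LDLR", "APOB", "LCAT"}))
        variants = self._random_variants(rng)
        base = {v.key for v in run_cascade(variants, cfg)[0]}
        perm = list(variants)
        rng.shuffle(perm)
        assert {v.key for v in run_cascade(perm, cfg)[0]} == base

    def test_monotone_in_thresholds(self, rng):
        variants = self._random_variants(rng)
        genes = frozenset({"LDLR", "APOB", "LCAT"})
        loose = {v.key for v in run_cascade(
            variants, FilterConfig(gene_list=genes, maf_cutoff=0.5))[0]}
        tight = {v.key for v in run_cascade(
            variants, FilterConfig(gene_list=genes, maf_cutoff=0.005))[0]}
        assert tight <= loose
        shallow = {v.key for v in run_cascade(
            variants, FilterConfig(gene_list=genes, min_depth=5))[0]}
        deep = {v.key for v in run_cascade(
            variants, FilterConfig(gene_list=genes, min_depth=40))[0]}
        assert deep <= shallow
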
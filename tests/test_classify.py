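"""Reference building, mismatch mapping (vs brute-force oracle) and
positional class assignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trfkin as tk
from trfkin.classify import (
    ReadMapping, TRNAGeneModel, build_reference, classify, collapse_and_count,
    map_sequence, revcomp,
)


def hamming_oracle(seq, reference, max_mm=1):
    """Independent scan of every reference substring (pure strings)."""
    out = []
    for ref in reference:
        m = len(seq)
        for i in range(len(ref.seq) - m + 1):
            if ref.kind == "mature_cca" and i + m <= len(ref.seq) - 3:
                continue  # interface rule: only CCA-overhanging placements
            window = ref.seq[i:i + m]
            mm = sum(1 for a, b in zip(window, seq)
                     if a != b or a == "N" or b == "N")
            if mm <= max_mm:
                out.append((ref.name, i, i + m, mm))
    if any(mm == 0 for *_, mm in out):
        out = [h for h in out if h[3] == 0]
    return sorted(out)


def as_tuples(hits):
    return sorted((h.ref_name, h.start, h.end, h.mismatches) for h in hits)


def plus_locus(seq_leader="ACGTACGTAA", seq_mature=None, seq_trailer="GACGTACGTACTTTT",
               intron=None, start=100, strand="+", locus_id="tL"):
    """Handcrafted locus; returns (genome, model, coding parts)."""
    rng = np.random.default_rng(42)
    if seq_mature is None:
        seq_mature = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 72)])
    if intron:
        mature_genomic = seq_mature[:38] + intron + seq_mature[38:]
    else:
        mature_genomic = seq_mature
    coding = seq_leader + mature_genomic + seq_trailer
    end = start + len(coding)
    pad5 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, start)])
    pad3 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
    if strand == "+":
        genome = {"chr1": pad5 + coding + pad3}
        leader = (start, start + len(seq_leader))
        if intron:
            b1 = (leader[1], leader[1] + 38)
            iv = (b1[1], b1[1] + len(intron))
            b2 = (iv[1], start + len(seq_leader) + len(mature_genomic))
            blocks = (b1, b2)
        else:
            blocks = ((leader[1], leader[1] + len(mature_genomic)),)
        trailer = (end - len(seq_trailer), end)
    else:
        genome = {"chr1": pad5 + revcomp(coding) + pad3}
        leader = (end - len(seq_leader), end)
        if intron:
            b1_tx = (len(seq_leader), len(seq_leader) + 38)
            iv_tx = (b1_tx[1], b1_tx[1] + len(intron))
            b2_tx = (iv_tx[1], len(seq_leader) + len(mature_genomic))
            blocks = tuple(sorted((end - e, end - s) for s, e in (b1_tx, b2_tx)))
        else:
            blocks = ((start + len(seq_trailer), end - len(seq_leader)),)
        trailer = (start, start + len(seq_trailer))
    model = TRNAGeneModel(locus_id, "chr1", strand, start, end,
                          leader, blocks, trailer)
    return genome, model, (seq_leader, seq_mature, seq_trailer)


class TestBuildReference:
    def test_plus_strand_transcript_is_genomic_substring(self):
        genome, model, _ = plus_locus()
        ref = build_reference(genome, [model])
        pre = next(r for r in ref if r.kind == "pre")
        assert pre.seq == genome["chr1"][model.start:model.end]

    def test_minus_strand_transcript_is_revcomp(self):
        genome, model, _ = plus_locus(strand="-")
        ref = build_reference(genome, [model])
        pre = next(r for r in ref if r.kind == "pre")
        assert pre.seq == revcomp(genome["chr1"][model.start:model.end])

    def test_spliced_mature_drops_intron(self):
        genome, model, (leader, mature, trailer) = plus_locus(intron="GTAAGTCATCAGTTTCAG")
        ref = build_reference(genome, [model])
        spliced = next(r for r in ref if r.kind == "mature")
        assert spliced.seq == mature
        assert "GTAAGTCATCAGTTTCAG" not in spliced.seq
        cca = next(r for r in ref if r.kind == "mature_cca")
        assert cca.seq == mature + "CCA"

    def test_out_of_bounds_names_locus(self):
        genome, model, _ = plus_locus()
        with pytest.raises(ValueError, match="tL"):
            build_reference({"chr1": genome["chr1"][:50]}, [model])
        with pytest.raises(ValueError, match="chromosome"):
            build_reference({"chr2": genome["chr1"]}, [model])


class TestMapSequence:
    def test_exact_trailer_match_single_hit(self):
        genome, model, (_, _, trailer) = plus_locus()
        ref = build_reference(genome, [model])
        query = trailer[:15]
        hits = map_sequence(query, ref)
        assert as_tuples(hits) == hamming_oracle(query, ref)
        assert len(hits) == 1 and hits[0].mismatches == 0

    def test_one_substitution_reported_as_mismatch(self):
        genome, model, (_, _, trailer) = plus_locus()
        ref = build_reference(genome, [model])
        query = trailer[:15]
        mutated = query[:7] + ("A" if query[7] != "A" else "G") + query[8:]
        hits = map_sequence(mutated, ref)
        assert len(hits) == 1 and hits[0].mismatches == 1
        assert as_tuples(hits) == hamming_oracle(mutated, ref)

    def test_paralogous_loci_give_two_mappings(self):
        rng = np.random.default_rng(0)
        mature = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 72)])
        g1, m1, _ = plus_locus(seq_mature=mature)
        g2 = {"chr1": g1["chr1"] + "TTTTTTTT" + g1["chr1"]}
        shift = len(g1["chr1"]) + 8
        m2 = TRNAGeneModel("tL2", "chr1", "+", m1.start + shift, m1.end + shift,
                           (m1.leader[0] + shift, m1.leader[1] + shift),
                           tuple((s + shift, e + shift) for s, e in m1.mature_blocks),
                           (m1.trailer[0] + shift, m1.trailer[1] + shift))
        ref = build_reference(g2, [m1, m2])
        query = mature[5:25]
        hits = map_sequence(query, ref)
        assert as_tuples(hits) == hamming_oracle(query, ref)
        assert {h.locus_id for h in hits} == {"tL", "tL2"}

    def test_rejects_invalid_characters(self):
        genome, model, _ = plus_locus()
        ref = build_reference(genome, [model])
        with pytest.raises(ValueError, match="non-ACGTN"):
            map_sequence("ACGTXACGTACGTAC", ref)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_oracle_equivalence_on_random_queries(self, data):
        genome, model, _ = plus_locus(intron="GTAAGCACTGATCGGTATCAG")
        mirnas = {"mir-x": "TAGCTTATCAGACTGATGTTGA"}
        ref = build_reference(genome, [model], mirnas)
        pre = next(r for r in ref if r.kind == "pre").seq
        # queries biased toward real substrings with mutations, plus noise
        kind = data.draw(st.sampled_from(["sub", "mut", "rand"]))
        length = data.draw(st.integers(15, 28))
        if kind == "rand":
            q = "".join(data.draw(st.lists(
                st.sampled_from("ACGT"), min_size=length, max_size=length)))
        else:
            start = data.draw(st.integers(0, len(pre) - length))
            q = pre[start:start + length]
            if kind == "mut":
                i = data.draw(st.integers(0, length - 1))
                b = data.draw(st.sampled_from("ACGTN"))
                q = q[:i] + b + q[i + 1:]
        assert as_tuples(map_sequence(q, ref)) == hamming_oracle(q, ref)


class TestClassify:
    @pytest.fixture()
    def toy(self):
        genome, model, parts = plus_locus(intron="GTAAGCACTGATCGGTATCAG")
        mirnas = {"mir-x": "TAGCTTATCAGACTGATGTTGA"}
        ref = build_reference(genome, [model], mirnas)
        return ref, model, parts

    def label_of(self, seq, ref):
        return classify(map_sequence(seq, ref), ref)[0]

    def test_trailer_fragment_is_trf1(self, toy):
        ref, model, (_, _, trailer) = toy
        assert self.label_of(trailer[:15], ref) == "tRF-1"

    def test_mature_start_fragment_is_trf5(self, toy):
        ref, model, (_, mature, _) = toy
        assert self.label_of(mature[0:18], ref) == "tRF-5"

    def test_mature_end_with_nontemplated_cca_is_trf3(self, toy):
        ref, model, (_, mature, _) = toy
        query = mature[-18:] + "CCA"
        hits = map_sequence(query, ref)
        label, basis = classify(hits, ref)
        assert label == "tRF-3"
        assert basis.cca_softclip

    def test_leader_fragment_is_trf_leader(self):
        genome, model, (leader, _, _) = plus_locus(seq_leader="ACGTACGTAAGGCCA")
        ref = build_reference(genome, [model])
        assert self.label_of(leader, ref) == "tRF-leader"

    def test_intron_fragment_is_intron_trf(self, toy):
        ref, model, _ = toy
        assert self.label_of("GTAAGCACTGATCGGTATCAG", ref) == "intron-tRF"

    def test_internal_mature_fragment_is_misc(self, toy):
        ref, model, (_, mature, _) = toy
        assert self.label_of(mature[10:28], ref) == "misc-tRF"

    def test_mirna_reference_hit_wins(self, toy):
        ref, *_ = toy
        assert self.label_of("TAGCTTATCAGACTGATGTTGA", ref) == "miRNA"

    def test_no_mapping_is_unassigned(self, toy):
        ref, *_ = toy
        label, basis = classify([], ref)
        assert label == "unassigned" and basis is None


class TestCollapse:
    def test_merges_identical_sequences(self):
        s1, s2 = "ACGTACGTACGTACG", "TGCATGCATGCATGC"
        out = collapse_and_count([s1, s1, s2])
        assert out == {s1: 2, s2: 1}

    def test_drops_reads_shorter_than_15(self):
        out = collapse_and_count(["ACGTACGTACGTAC"])  # 14 nt
        assert out == {}

    def test_total_count_conserved_after_length_filter(self):
        rng = np.random.default_rng(3)
        pool = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, L)])
                for L in rng.integers(12, 25, 50)]
        stream = [pool[i] for i in rng.integers(0, 50, 10_000)]
        out = collapse_and_count(stream)
        expected = sum(1 for s in stream if len(s) >= 15)
        assert sum(out.values()) == expected


class TestPipelineProperties:
    def test_partition_and_recovery_on_generator_output(self, small_params):
        # noise-free recovery: no 3' jitter, every truth class recovered
        import dataclasses
        p = dataclasses.replace(small_params, trf1_end_jitter=0)
        d = tk.simulate_dataset(p)
        ref = build_reference(d.genome, d.models, d.mirnas)
        tab = d.truth.table[d.truth.table["true_class"] != "spike-in"]
        collapsed = collapse_and_count([(r.sequence, 5) for r in tab.itertuples()])
        res = tk.classify_reads(collapsed, ref)
        assert sum(r.count for r in res) == 5 * len(tab)
        truth_class = tab.set_index("sequence")["true_class"]
        agree = [r.assigned_class == truth_class[r.sequence] for r in res]
        assert np.mean(agree) >= 0.99

    def test_one_mismatch_mutation_keeps_assignment(self, small_data):
        d = small_data
        ref = build_reference(d.genome, d.models, d.mirnas)
        tab = d.truth.table[d.truth.table["true_class"] != "spike-in"]
        rng = np.random.default_rng(9)
        changed = 0
        for row in tab.itertuples():
            base = classify(map_sequence(row.sequence, ref), ref)[0]
            i = len(row.sequence) // 2
            alt = "ACGT"[(("ACGT".index(row.sequence[i])) + 1) % 4]
            mutated = row.sequence[:i] + alt + row.sequence[i + 1:]
            got = classify(map_sequence(mutated, ref), ref)[0]
            changed += got != base
        assert changed / len(tab) <= 0.01

    def test_strand_symmetry(self, small_data):
        d = small_data
        L = len(d.genome["chrT"])
        flipped_genome = {"chrT": revcomp(d.genome["chrT"])}
        flipped_models = []
        for m in d.models:
            flip = lambda iv: (L - iv[1], L - iv[0])
            flipped_models.append(TRNAGeneModel(
                m.locus_id, m.chrom, "-" if m.strand == "+" else "+",
                L - m.end, L - m.start, flip(m.leader),
                tuple(sorted(flip(b) for b in m.mature_blocks)),
                flip(m.trailer)))
        ref_a = build_reference(d.genome, d.models, d.mirnas)
        ref_b = build_reference(flipped_genome, flipped_models, d.mirnas)
        for seq in d.truth.table["sequence"].head(40):
            a = classify(map_sequence(seq, ref_a), ref_a)[0]
            b = classify(map_sequence(seq, ref_b), ref_b)[0]
            assert a == b
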
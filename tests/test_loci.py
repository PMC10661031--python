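"""Integration-locus selection: distance-rule scanning vs a per-base oracle,
target picking, homology arms, repeat diagnostics, conservation filter."""

import random
import warnings

import numpy as np
import pytest

from multigate.fixtures import FixtureConfig, generate_toy_genome
from multigate.loci import (
    LocusDesignError,
    design_loci,
    extract_homology_arms,
    longest_shared_repeat,
    pick_target_site,
    scan_intergenic,
)
from multigate.seqcore import SequenceRecord, revcomp


def brute_force_windows(genome, annotation, start_thr=1000, stop_thr=500,
                        blacklist=("tRNA",)):
    """Independent per-base check of every distance rule."""
    out = []
    for rec in genome:
        genes = [a for a in annotation
                 if a["seqid"] == rec.id and a["kind"] == "gene"
                 and a.get("strand") in "+-"]
        black = [a for a in annotation
                 if a["seqid"] == rec.id and a["kind"] in blacklist]
        allowed = []
        for x in range(len(rec.bases)):
            ok = all(not (b["start"] <= x < b["end"]) for b in black)
            for g in genes:
                if g["start"] <= x < g["end"]:
                    ok = False
                    break
                if g["strand"] == "+":
                    c_start, c_stop = g["start"], g["end"] - 3
                else:
                    c_start, c_stop = g["end"] - 1, g["start"] + 2
                if abs(x - c_start) <= start_thr or abs(x - c_stop) <= stop_thr:
                    ok = False
                    break
            allowed.append(ok)
        x = 0
        while x < len(allowed):
            if allowed[x]:
                y = x
                while y < len(allowed) and allowed[y]:
                    y += 1
                out.append((rec.id, x, y))
                x = y
            else:
                x += 1
    return sorted(out)


def test_scan_matches_brute_force_on_toy_genome(toy_genome):
    got = scan_intergenic(toy_genome.records, toy_genome.annotation)
    assert got == brute_force_windows(toy_genome.records, toy_genome.annotation)


def test_scan_recovers_planted_truth(toy_genome):
    got = scan_intergenic(toy_genome.records, toy_genome.annotation)
    want = sorted((t["chrom"], t["window_start"], t["window_end"])
                  for t in toy_genome.truth)
    assert got == want


def test_planted_targets_rank_first(toy_genome):
    for t in toy_genome.truth:
        window = (t["chrom"], t["window_start"], t["window_end"])
        candidates = pick_target_site(window, toy_genome.records)
        assert candidates, f"no candidate in {window}"
        top = candidates[0]
        assert (top.protospacer, top.pam, top.position, top.strand) == \
            (t["protospacer"], t["pam"], t["position"], t["strand"])


def test_position_900bp_from_start_codon_excluded():
    rec = SequenceRecord("c", "A" * 5000)
    genes = [{"seqid": "c", "kind": "gene", "start": 3000, "end": 4000,
              "strand": "+"}]
    windows = scan_intergenic([rec], genes)
    # 3000-900=2100 is within 1 kb of the start codon at 3000 -> excluded
    assert all(not (s <= 2100 < e) for _, s, e in windows)
    assert any(s <= 1999 < e for _, s, e in windows)  # 1001 bp away: allowed


def test_minus_strand_codons():
    rec = SequenceRecord("c", "A" * 6000)
    genes = [{"seqid": "c", "kind": "gene", "start": 2000, "end": 3000,
              "strand": "-"}]
    windows = scan_intergenic([rec], genes)
    # start codon at 2999, stop codon at 2002
    assert windows == [("c", 0, 1502), ("c", 4000, 6000)]


def test_empty_annotation_whole_chromosome(toy_genome):
    windows = scan_intergenic(toy_genome.records, [])
    assert windows == sorted((r.id, 0, len(r.bases)) for r in toy_genome.records)


def test_gene_without_strand_warns():
    rec = SequenceRecord("c", "A" * 3000)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        windows = scan_intergenic(
            [rec], [{"seqid": "c", "kind": "gene", "start": 1000, "end": 2000,
                     "strand": "."}])
    assert any("no strand" in str(w.message) for w in caught)
    assert windows == [("c", 0, 3000)]


def test_blacklist_kind_excluded():
    rec = SequenceRecord("c", "A" * 2000)
    ann = [{"seqid": "c", "kind": "tRNA", "start": 500, "end": 600,
            "strand": "+"}]
    windows = scan_intergenic([rec], ann)
    assert windows == [("c", 0, 500), ("c", 600, 2000)]


def test_threshold_monotonicity(toy_genome):
    """Raising either threshold never enlarges any window."""
    def coverage(start_thr, stop_thr):
        return {(c, x) for c, s, e in
                scan_intergenic(toy_genome.records, toy_genome.annotation,
                                start_thr, stop_thr)
                for x in range(s, e)}

    base = coverage(1000, 500)
    assert coverage(1200, 500) <= base
    assert coverage(1000, 700) <= base
    assert coverage(1200, 700) <= coverage(1200, 500)


def test_window_without_pam_is_empty():
    rec = SequenceRecord("c", "ATATATATAT" * 10)
    assert pick_target_site(("c", 0, 100), [rec]) == []


def test_duplicated_protospacer_rejected():
    cfg = FixtureConfig(seed=23, duplicate_protospacer_locus=0)
    genome = generate_toy_genome(cfg)
    t = genome.truth[0]
    window = (t["chrom"], t["window_start"], t["window_end"])
    candidates = pick_target_site(window, genome.records)
    assert all(c.protospacer != t["protospacer"] for c in candidates)


def test_homology_arm_coordinates(toy_genome):
    rec = toy_genome.records[0]
    arm5, arm3 = extract_homology_arms(rec, 5000, 500)
    assert (arm5.start, arm5.end) == (4500, 5000)
    assert (arm3.start, arm3.end) == (5000, 5500)
    assert arm5.sequence == rec.bases[4500:5000]
    with pytest.raises(LocusDesignError, match="flank"):
        extract_homology_arms(rec, 300, 500)


def test_non_unique_arm_warns():
    core = "".join(random.Random(5).choice("ACGT") for _ in range(600))
    rec = SequenceRecord("c", core + "T" * 50 + core)  # planted duplication
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        extract_homology_arms(rec, 300, 200, genome=[rec])
    assert any("not" in str(w.message) and "unique" in str(w.message)
               for w in caught)


# -- longest shared repeat ----------------------------------------------------


def dp_longest_common_substring(a, b):
    """O(n^2) dynamic-programming oracle."""
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def test_repeat_planted_block():
    r = random.Random(11)
    a = "".join(r.choice("ACGT") for _ in range(500))
    b = "".join(r.choice("ACGT") for _ in range(500))
    block = "".join(r.choice("ACGT") for _ in range(24))
    sa, sb = a[:250] + block + a[250:], b[:100] + block + b[100:]
    length, pair, sub, rc = longest_shared_repeat([sa, sb])
    assert length == max(24, dp_longest_common_substring(sa, sb))
    assert not rc and sub in sa and sub in sb


def test_repeat_identical_sequences():
    s = "ACGTACGTGGCA" * 10
    length, pair, sub, rc = longest_shared_repeat([s, s])
    assert length == len(s) and sub == s


def test_repeat_reverse_complement_planting():
    r = random.Random(13)
    a = "".join(r.choice("ACGT") for _ in range(400))
    b = "".join(r.choice("ACGT") for _ in range(400))
    block = "".join(r.choice("ACGT") for _ in range(24))
    sa, sb = a[:200] + block + a[200:], b[:50] + revcomp(block) + b[50:]
    length, pair, sub, rc = longest_shared_repeat([sa, sb])
    fwd_best = dp_longest_common_substring(sa, sb)
    rev_best = dp_longest_common_substring(sa, revcomp(sb))
    assert rev_best >= 24
    assert length == max(fwd_best, rev_best)
    assert rc == (rev_best > fwd_best)


@pytest.mark.parametrize("seed", range(8))
def test_repeat_matches_dp_oracle(seed):
    r = random.Random(seed)
    a = "".join(r.choice("ACGT") for _ in range(200))
    b = "".join(r.choice("ACGT") for _ in range(200))
    length, _, _, rc = longest_shared_repeat([a, b], include_revcomp=False)
    assert length == dp_longest_common_substring(a, b)


def test_conservation_filter_drops_mutated_locus(toy_genome):
    """A single SNP in one strain's homology arm removes that candidate."""
    strain = [SequenceRecord(r.id, r.bases, r.topology)
              for r in toy_genome.records]
    t = toy_genome.truth[0]
    rec = next(r for r in strain if r.id == t["chrom"])
    pos = t["cut_position"] - 100  # inside the 5' arm
    mutated = rec.bases[:pos] + ("A" if rec.bases[pos] != "A" else "C") \
        + rec.bases[pos + 1:]
    strain = [SequenceRecord(r.id, mutated if r.id == t["chrom"] else r.bases,
                             r.topology) for r in strain]
    full = design_loci(toy_genome.records, toy_genome.annotation)
    filtered = design_loci(toy_genome.records, toy_genome.annotation,
                           extra_genomes=[strain])
    assert len(full) == len(toy_genome.truth)
    dropped = {c.chrom for c in full} - {c.chrom for c in filtered} or \
        {(c.chrom, c.window) for c in full} - {(c.chrom, c.window) for c in filtered}
    assert len(full) - len(filtered) == 1
    assert (t["chrom"], (t["window_start"], t["window_end"])) in \
        {(c.chrom, c.window) for c in full}
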
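"""Structure reading, pLDDT extraction, and domain-to-chain mapping."""

import itertools

import numpy as np
import pytest

from cathsf import (
    AlignmentMapping,
    StructureModel,
    extract_mean_plddt,
    map_domain_to_chain,
    read_structure,
    trim_to_domain,
    write_structure,
)
from cathsf.errors import (
    ChainNotFoundError,
    ConfigurationError,
    IntegrityError,
    MappingFailureError,
    StructureParseError,
)
from cathsf.structure_io import Residue

PDB_5RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 50.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00 51.00           C
ATOM      3  CA  CYS A   2       2.300   2.100   1.500  1.00 52.00           C
ATOM      4  CA  ASP A   3       0.500   3.900   3.000  1.00 53.00           C
ATOM      5  CA  GLU A   4      -1.900   3.100   4.500  1.00 54.00           C
ATOM      6  CA  PHE A   5      -2.200   0.600   6.000  1.00 55.00           C
HETATM    7  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O
END
"""


@pytest.fixture()
def pdb_file(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(PDB_5RES)
    return str(p)


def make_model(bfactors, kind="predicted", seq=None, coords=None):
    n = len(bfactors)
    seq = seq or "A" * n
    coords = coords if coords is not None else [(3.8 * i, 0.0, 0.0)
                                                for i in range(n)]
    return StructureModel(
        structure_id="toy", chain_id="A",
        residues=tuple(Residue(i + 1, "", seq[i], tuple(coords[i]),
                               float(bfactors[i])) for i in range(n)),
        source_kind=kind,
    )


class TestReadStructure:
    def test_reads_calpha_trace_in_order(self, pdb_file):
        m = read_structure(pdb_file, "A")
        assert len(m) == 5
        assert m.sequence == "ACDEF"
        assert m.bfactors().tolist() == [51.0, 52.0, 53.0, 54.0, 55.0]
        assert [r.seqid for r in m.residues] == [1, 2, 3, 4, 5]

    def test_water_hetatm_ignored(self, pdb_file):
        m = read_structure(pdb_file, "A")
        assert all(r.aa_code != "X" for r in m.residues)

    def test_absent_chain_raises(self, pdb_file):
        with pytest.raises(ChainNotFoundError, match="Z"):
            read_structure(pdb_file, "Z")

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(StructureParseError):
            read_structure(str(tmp_path / "nope.pdb"), "A")

    def test_generator_round_trip(self, structure_set):
        """Files written by the generator read back to its own records."""
        _, truths = structure_set
        written = [t for t in truths if t.path is not None]
        assert written
        for t in written:
            m = read_structure(t.path, "A", source_kind="predicted")
            assert len(m) == t.n_residues
            assert m.sequence == t.sequence
            np.testing.assert_allclose(m.bfactors(), t.bfactors, atol=0.01)

    def test_write_read_round_trip(self, tmp_path):
        m = make_model([80, 81, 82], seq="ACD")
        path = tmp_path / "rt.pdb"
        write_structure(m, str(path))
        back = read_structure(str(path), "A", source_kind="predicted")
        assert back.sequence == "ACD"
        np.testing.assert_allclose(back.bfactors(), m.bfactors(), atol=0.01)


class TestStructureModelInvariants:
    def test_unsorted_residues_rejected(self):
        with pytest.raises(IntegrityError, match="ordered"):
            StructureModel("x", "A", residues=(
                Residue(2, "", "A", (0, 0, 0), 50.0),
                Residue(1, "", "A", (3.8, 0, 0), 50.0)))

    def test_predicted_bfactor_bounds(self):
        with pytest.raises(IntegrityError, match="pLDDT"):
            make_model([150.0, 50.0])

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(IntegrityError, match="finite"):
            make_model([50, 50], coords=[(0, 0, 0), (np.nan, 0, 0)])


class TestMeanPlddt:
    def test_mean_of_three(self):
        assert extract_mean_plddt(make_model([10, 20, 30])) == 20.0

    def test_constant_profile_with_mapping(self):
        m = make_model([84.0] * 6)
        mapping = AlignmentMapping("d", (1, 2, 3), 1.0, 1.0)
        assert extract_mean_plddt(m, mapping) == 84.0

    def test_mapped_subset_matches_brute_force(self, rng):
        b = rng.uniform(30, 95, 50)
        m = make_model(b)
        mapping = AlignmentMapping("d", tuple(range(10, 20)), 1.0, 1.0)
        expected = sum(b[i] for i in range(10, 20)) / 10  # independent sum
        assert extract_mean_plddt(m, mapping) == pytest.approx(expected)

    def test_experimental_raises(self):
        with pytest.raises(ConfigurationError, match="experimental"):
            extract_mean_plddt(make_model([10.0], kind="experimental"))

    def test_permutation_invariant_and_bounded(self, rng):
        b = rng.uniform(0, 100, 30)
        m1 = make_model(b)
        perm = rng.permutation(30)
        m2 = make_model(b[perm])
        assert extract_mean_plddt(m1) == pytest.approx(extract_mean_plddt(m2))
        assert b.min() <= extract_mean_plddt(m1) <= b.max()


def brute_force_local_alignment(domain, chain, match=1.0, mismatch=-1.0,
                                gap_open=-5.0, gap_extend=-0.5):
    """Exhaustive local affine-gap alignment for tiny sequences.

    Enumerates every pair of equal-length increasing index tuples
    (domain positions, chain positions) forming a contiguous local
    window, scoring matches/mismatches plus affine penalties for gaps
    strictly inside the window.  Returns (best score, aligned pairs).
    """
    best = (0.0, ())
    nd, nc = len(domain), len(chain)
    for k in range(1, min(nd, nc) + 1):
        for dpos in itertools.combinations(range(nd), k):
            for cpos in itertools.combinations(range(nc), k):
                score = sum(match if domain[d] == chain[c] else mismatch
                            for d, c in zip(dpos, cpos))
                for prev, nxt in zip(dpos, dpos[1:]):
                    gap = nxt - prev - 1
                    if gap:
                        score += gap_open + gap_extend * (gap - 1)
                for prev, nxt in zip(cpos, cpos[1:]):
                    gap = nxt - prev - 1
                    if gap:
                        score += gap_open + gap_extend * (gap - 1)
                if score > best[0]:
                    best = (score, tuple(zip(dpos, cpos)))
    return best


class TestMapDomainToChain:
    def test_exact_substring(self):
        m = make_model([50] * 8, seq="MMACDEKK")
        mp = map_domain_to_chain("ACDE", m)
        assert mp.chain_positions == (2, 3, 4, 5)
        assert mp.coverage == 1.0 and mp.identity == 1.0

    def test_unresolved_residue_fails_with_achieved_values(self):
        """A chain missing a residue drops coverage below the threshold;
        the error carries what the exhaustive alignment oracle achieves."""
        m = make_model([50] * 7, seq="MMACEKK")
        with pytest.raises(MappingFailureError) as exc:
            map_domain_to_chain("ACDE", m, domain_id="d1")
        score, pairs = brute_force_local_alignment("ACDE", "MMACEKK")
        assert exc.value.coverage == pytest.approx(len(pairs) / 4)
        assert exc.value.coverage < 0.9

    def test_identity_mapping_on_full_chain(self):
        m = make_model([50] * 6, seq="ACDEFG")
        mp = map_domain_to_chain("ACDEFG", m)
        assert mp.chain_positions == tuple(range(6))

    def test_relaxed_thresholds_accept_partial(self):
        m = make_model([50] * 7, seq="MMACEKK")
        mp = map_domain_to_chain("ACDE", m, min_coverage=0.25,
                                 min_identity=0.5)
        assert 0.25 <= mp.coverage <= 1.0

    def test_agrees_with_exhaustive_oracle(self, rng):
        """Accepted mappings reproduce the brute-force optimum's pairs."""
        for _ in range(5):
            chain = "".join(rng.choice(list("ACDEFGHIK"), size=9))
            start = int(rng.integers(0, 5))
            domain = chain[start:start + 4]
            m = make_model([50] * 9, seq=chain)
            mp = map_domain_to_chain(domain, m)
            score, pairs = brute_force_local_alignment(domain, chain)
            aligner_pairs = tuple((d, c) for d, c
                                  in enumerate(mp.chain_positions)
                                  if c is not None)
            my_score = sum(1.0 if domain[d] == chain[c] else -1.0
                           for d, c in aligner_pairs)
            assert my_score == pytest.approx(score)


class TestTrim:
    def test_slice_semantics(self):
        m = make_model([50] * 8, seq="MMACDEKK")
        mapping = AlignmentMapping("d", (2, 3, 4, 5), 1.0, 1.0)
        t = trim_to_domain(m, mapping)
        assert t.sequence == "ACDE"
        assert [r.seqid for r in t.residues] == [3, 4, 5, 6]  # original ids

    def test_identity_mapping_is_noop(self):
        m = make_model([50] * 5, seq="ACDEF")
        mapping = AlignmentMapping("d", tuple(range(5)), 1.0, 1.0)
        assert trim_to_domain(m, mapping).residues == m.residues

    def test_trim_then_remap_is_identity(self, structure_set):
        _, truths = structure_set
        t = next(t for t in truths if t.path)
        m = read_structure(t.path, "A", source_kind="predicted")
        mp = map_domain_to_chain(t.sequence[5:25], m, domain_id=t.domain_id)
        trimmed = trim_to_domain(m, mp)
        again = map_domain_to_chain(trimmed.sequence, trimmed)
        assert again.chain_positions == tuple(range(len(trimmed)))

    def test_subset_order_preserved(self, rng):
        m = make_model(rng.uniform(20, 90, 12))
        idx = tuple(sorted(rng.choice(12, size=5, replace=False).tolist()))
        t = trim_to_domain(m, AlignmentMapping("d", idx, 1.0, 1.0))
        assert all(r in m.residues for r in t.residues)
        positions = [m.residues.index(r) for r in t.residues]
        assert positions == sorted(positions)

    def test_out_of_range_mapping_rejected(self):
        m = make_model([50] * 4)
        with pytest.raises(IntegrityError):
            trim_to_domain(m, AlignmentMapping("d", (2, 9), 1.0, 1.0))
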
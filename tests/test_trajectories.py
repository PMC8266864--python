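import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import natraj as nj
from natraj.errors import ValidationError
from conftest import make_deg_list


class TestClassifyArm:
    @pytest.mark.parametrize(
        "log2fc,p,expected",
        [
            (0.584, 0.049, "up"),       # boundary fold change is inclusive
            (0.584, 0.05, "stable"),    # p threshold is strict
            (2.0, 0.10, "stable"),      # big fold change, non-significant p
            (-0.584, 0.01, "stable"),   # down requires strictly < -0.584
            (-0.585, 0.01, "down"),
            (-3.0, 0.2, "stable"),
            (0.0, 0.001, "stable"),
        ],
    )
    def test_boundaries(self, log2fc, p, expected):
        assert nj.classify_arm(log2fc, p) == expected

    @given(
        log2fc=st.one_of(
            st.floats(-5, 5, allow_nan=False),
            st.sampled_from([0.584, -0.584, 0.58496250072, -0.58496250072]),
        ),
        p=st.one_of(
            st.floats(1e-12, 1.0, exclude_min=False),
            st.sampled_from([0.05, 0.049999999, 1.0]),
        ),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_total_partition(self, log2fc, p):
        """Exactly one of up/down/stable for every (log2fc, p) pair."""
        result = nj.classify_arm(log2fc, p)
        assert result in ("up", "down", "stable")
        if result == "up":
            assert p < 0.05 and log2fc >= 0.584
        elif result == "down":
            assert p < 0.05 and log2fc < -0.584
        else:
            assert not (p < 0.05 and log2fc >= 0.584)
            assert not (p < 0.05 and log2fc < -0.584)


class TestClassifyTrajectories:
    def arm2(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj"])
        return df.set_index("gene_id")

    def test_example_patterns(self):
        degs = make_deg_list(["a", "b"], [1.0, -1.0], [0.001, 0.001])
        arm2 = self.arm2([("a", 0.0, 0.9), ("b", 0.7, 0.01)])
        table, counts, missing = nj.classify_trajectories(degs, arm2)
        assert table.loc["a", "pattern"] == "up-stable"
        assert table.loc["b", "pattern"] == "down-up"
        assert missing == []

    def test_counts_partition_classified_genes(self):
        rng = np.random.default_rng(4)
        n = 200
        genes = [f"g{i}" for i in range(n)]
        lfc1 = rng.choice([1.2, -1.2], n)
        degs = make_deg_list(genes, lfc1, rng.uniform(1e-6, 0.049, n))
        arm2 = self.arm2(
            [(g, rng.normal(0, 1.0), rng.uniform(1e-6, 1.0)) for g in genes]
        )
        table, counts, _ = nj.classify_trajectories(degs, arm2)
        assert counts.sum() == len(table) == n
        assert set(table["pattern"]) <= set(nj.PATTERNS)

    def test_missing_arm2_genes_excluded_not_stable(self):
        degs = make_deg_list(["a", "b"], [1.0, 1.0], [0.01, 0.01])
        arm2 = self.arm2([("a", 1.0, 0.01)])
        with pytest.warns(UserWarning, match="absent"):
            table, counts, missing = nj.classify_trajectories(degs, arm2)
        assert missing == ["b"]
        assert counts.sum() == 1


class TestOverlap:
    def test_two_list_counts(self):
        a = make_deg_list(["a", "b", "c"], [1, 1, 1], [0.01] * 3, contrast="A")
        b = make_deg_list(["b", "c", "d"], [1, -1, 1], [0.01] * 3, contrast="B")
        report = nj.overlap([a, b])
        assert report.region_counts[("A",)] == 1
        assert report.region_counts[("B",)] == 1
        assert report.region_counts[("A", "B")] == 2
        assert report.union_size == 4
        shared, same, opposite = report.pairwise_direction[("A", "B")]
        assert (shared, same, opposite) == (2, 1, 1)

    def test_identical_lists(self):
        a = make_deg_list(["x", "y"], [1, -1], [0.01, 0.01], contrast="A")
        b = make_deg_list(["x", "y"], [1, -1], [0.01, 0.01], contrast="B")
        report = nj.overlap([a, b])
        assert report.region_counts[("A", "B")] == 2
        assert report.union_size == 2

    def test_three_lists_match_bruteforce_enumeration(self):
        rng = np.random.default_rng(12)
        universe = [f"g{i}" for i in range(60)]
        lists = []
        for label in "ABC":
            ids = sorted(rng.choice(universe, size=rng.integers(5, 40),
                                    replace=False))
            lists.append(make_deg_list(ids, [1.0] * len(ids), [0.01] * len(ids),
                                       contrast=label))
        report = nj.overlap(lists)
        sets = {lst.contrast: set(lst.gene_ids) for lst in lists}
        for r in range(1, 4):
            for inside in itertools.combinations("ABC", r):
                expected = set(universe)
                for lab in "ABC":
                    expected &= sets[lab] if lab in inside else (set(universe) - sets[lab])
                assert report.region_counts[inside] == len(expected)
        assert report.union_size == len(set.union(*sets.values()))
        assert sum(report.region_counts.values()) == report.union_size

    def test_duplicate_ids_rejected(self):
        table = pd.DataFrame({"log2fc": [1.0, 1.0], "padj": [0.01, 0.01],
                              "direction": ["up", "up"]},
                             index=pd.Index(["a", "a"], name="gene_id"))
        bad = nj.DEGList(contrast="A", table=table)
        ok = make_deg_list(["a", "b"], [1, 1], [0.01, 0.01], contrast="B")
        with pytest.raises(ValidationError, match="duplicate"):
            nj.overlap([bad, ok])


class TestBiotypeComposition:
    def ann(self, mapping):
        df = pd.DataFrame(
            {"gene_id": list(mapping), "symbol": list(mapping),
             "biotype": list(mapping.values()), "chromosome": "1"}
        )
        return df.set_index("gene_id", drop=False)

    def test_counts_percentages_and_updown_split(self):
        genes = [f"c{i}" for i in range(6)] + [f"n{i}" for i in range(4)]
        lfc = [1, 1, 1, 1, -1, -1] + [1, 1, -1, -1]
        degs = make_deg_list(genes, lfc, [0.01] * 10)
        mapping = {g: "protein_coding" for g in genes[:6]}
        mapping.update({g: "lincRNA" for g in genes[6:]})
        report = nj.biotype_composition(degs, self.ann(mapping))
        assert report.total == 10
        assert report.coding_total == 6
        assert report.coding_up == 4
        assert report.coding_up_percent == 66.7
        coding_row = report.table[report.table["biotype"] == "protein_coding"]
        assert coding_row["percent"].iloc[0] == 60.0
        assert report.noncoding_total == 4

    def test_unannotated_counted_as_unknown(self):
        degs = make_deg_list(["a", "b"], [1, 1], [0.01, 0.01])
        report = nj.biotype_composition(degs, self.ann({"a": "snoRNA"}))
        assert set(report.table["biotype"]) == {"snoRNA", "unknown"}

    def test_empty_list(self):
        degs = make_deg_list([], [], [])
        report = nj.biotype_composition(degs, self.ann({}))
        assert report.total == 0 and len(report.table) == 0


class TestChromosomeComposition:
    def test_shares(self):
        ann = pd.DataFrame(
            {"gene_id": ["a", "b", "c", "d"], "symbol": "s",
             "biotype": "protein_coding",
             "chromosome": ["Y", "Y", "X", "7"]}
        ).set_index("gene_id", drop=False)
        report = nj.chromosome_composition(["a", "b", "c", "d"], ann)
        as_dict = dict(zip(report["chromosome_class"], report["percent"]))
        assert as_dict["Y"] == 50.0
        assert as_dict["X"] == 25.0
        assert as_dict["autosome"] == 25.0
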
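import collections
import json

import pytest

from pfb.convert import from_json, to_json, validate_records
from pfb.errors import NameCollisionError, UnknownNodeError, UnknownPropertyError
from pfb.pfb_io import read_entities, read_metadata
from pfb.schema_compiler import dictionary_from_parts
from pfb.transform import (
    rename_node,
    rename_property,
    retarget_ontology,
    rewrite_reference,
)

from conftest import make_sim_batch, write_batch


def payload_multisets(path):
    """Per-node multiset of payload values, the transform conservation metric."""
    out = collections.defaultdict(collections.Counter)
    for e in read_entities(path):
        for v in e.object.values():
            out[e.name][json.dumps(v)] += 1
    return dict(out)


class TestRenameNode:
    def test_all_entities_carry_new_name(self, tmp_path, demographic_dict,
                                         demographic_records):
        entities, _ = from_json(demographic_dict, demographic_records)
        src = write_batch(tmp_path, demographic_dict, entities)
        dst = tmp_path / "renamed.pfb"
        summary = rename_node(src, dst, "demographic", "subject")
        assert summary.entities_written == 2 and summary.entities_changed == 2
        schema, metadata = read_metadata(dst)
        d2 = dictionary_from_parts(schema, metadata)
        assert d2.node_names == ["subject"]
        back = list(read_entities(dst))
        assert all(e.name == "subject" for e in back)
        assert validate_records(d2, back) == []

    def test_child_relations_follow_parent_rename(self, tmp_path):
        d, _, entities = make_sim_batch(seed=20, n_nodes=5, records_per_node=8)
        src = write_batch(tmp_path, d, entities)
        dst = tmp_path / "renamed.pfb"
        root = d.nodes[0].name
        rename_node(src, dst, root, "renamed_root")
        stale = [r for e in read_entities(dst) for r in e.relations
                 if r.dst_name == root]
        assert stale == []
        schema, metadata = read_metadata(dst)
        assert validate_records(dictionary_from_parts(schema, metadata),
                                list(read_entities(dst))) == []

    def test_rename_to_existing_name_collides(self, tmp_path):
        d, _, entities = make_sim_batch(seed=21, n_nodes=3)
        src = write_batch(tmp_path, d, entities)
        with pytest.raises(NameCollisionError):
            rename_node(src, tmp_path / "x.pfb", d.nodes[0].name,
                        d.nodes[1].name)

    def test_rename_unknown_node(self, tmp_path):
        d, _, entities = make_sim_batch(seed=22, n_nodes=3)
        src = write_batch(tmp_path, d, entities)
        with pytest.raises(UnknownNodeError):
            rename_node(src, tmp_path / "x.pfb", "ghost", "anything")

    def test_inverse_rename_restores_canonical_file(self, tmp_path):
        d, _, entities = make_sim_batch(seed=23, n_nodes=6)
        src = write_batch(tmp_path, d, entities)
        mid, back = tmp_path / "mid.pfb", tmp_path / "back.pfb"
        node = d.nodes[2].name
        rename_node(src, mid, node, "temporarily_renamed")
        rename_node(mid, back, "temporarily_renamed", node)
        s0, m0 = read_metadata(src)
        s1, m1 = read_metadata(back)
        assert s0.canonical_form() == s1.canonical_form()
        assert m0 == m1
        assert list(read_entities(src)) == list(read_entities(back))


class TestRenameProperty:
    def test_round_trip_json_shows_new_key(self, tmp_path, demographic_dict,
                                           demographic_records):
        entities, _ = from_json(demographic_dict, demographic_records)
        src = write_batch(tmp_path, demographic_dict, entities)
        dst = tmp_path / "renamed.pfb"
        rename_property(src, dst, "demographic", "gender", "sex")
        back = to_json(dst)
        assert all("sex" in rec and "gender" not in rec
                   for rec in back["demographic"])

    def test_values_untouched(self, tmp_path):
        d, _, entities = make_sim_batch(seed=24, n_nodes=4, records_per_node=15)
        src = write_batch(tmp_path, d, entities)
        dst = tmp_path / "renamed.pfb"
        node = d.nodes[1].name
        before = payload_multisets(src)
        rename_property(src, dst, node, "prop_00", "renamed_prop")
        assert payload_multisets(dst) == before

    def test_collision_and_unknowns(self, tmp_path, demographic_dict,
                                    demographic_records):
        entities, _ = from_json(demographic_dict, demographic_records)
        src = write_batch(tmp_path, demographic_dict, entities)
        out = tmp_path / "x.pfb"
        with pytest.raises(NameCollisionError):
            rename_property(src, out, "demographic", "gender", "age")
        with pytest.raises(UnknownPropertyError):
            rename_property(src, out, "demographic", "ghost", "anything")
        with pytest.raises(UnknownNodeError):
            rename_property(src, out, "ghost", "gender", "sex")


CDISC = "https://www.cdisc.org/terms/"
NCIT = "http://purl.obolibrary.org/obo/NCIT_"


class TestRetargetOntology:
    def _cdisc_file(self, tmp_path):
        d, _, entities = make_sim_batch(seed=25, n_nodes=4)
        for n in d.nodes:
            n.ontology_reference = f"{CDISC}{n.name}"
            for p in n.properties:
                p.ontology_reference = f"{CDISC}{n.name}.{p.name}"
                p.values["ontology_reference"] = f"{CDISC}v/{p.name}"
        return d, write_batch(tmp_path, d, entities)

    def test_vocabulary_swap(self, tmp_path):
        d, src = self._cdisc_file(tmp_path)
        dst = tmp_path / "ncit.pfb"
        summary = retarget_ontology(src, dst, {CDISC: NCIT})
        _, metadata = read_metadata(dst)
        for nm in metadata.nodes.values():
            assert nm.ontology_reference.startswith(NCIT)
            for pm in nm.properties.values():
                assert pm.ontology_reference.startswith(NCIT)
                assert pm.values["ontology_reference"].startswith(NCIT)
        # 1 node ref + per property (ref + values entry)
        expected = len(d.nodes) + 2 * sum(len(n.properties) for n in d.nodes)
        assert summary.total_references == expected
        assert payload_multisets(src) == payload_multisets(dst)

    def test_empty_mapping_is_identity(self, tmp_path):
        _, src = self._cdisc_file(tmp_path)
        dst = tmp_path / "same.pfb"
        summary = retarget_ontology(src, dst, {})
        assert summary.total_references == 0
        s0, m0 = read_metadata(src)
        s1, m1 = read_metadata(dst)
        assert s0.canonical_form() == s1.canonical_form() and m0 == m1
        assert list(read_entities(src)) == list(read_entities(dst))

    def test_longest_prefix_wins(self):
        mapping = {"http://a/": "http://SHORT/", "http://a/b/": "http://LONG/"}
        refs = ["http://a/x", "http://a/b/x", "http://a/b/", "http://c/x"]
        for ref in refs:
            got, hit = rewrite_reference(ref, mapping)
            # brute-force single-reference oracle
            matches = [p for p in mapping if ref.startswith(p)]
            if matches:
                best = max(matches, key=len)
                assert hit and got == mapping[best] + ref[len(best):]
            else:
                assert not hit and got == ref


def test_transforms_conserve_counts_and_values(tmp_path):
    """Entity counts and payload multisets survive all three transforms."""
    for seed in range(5):
        d, _, entities = make_sim_batch(seed=seed, n_nodes=5, records_per_node=10)
        src = write_batch(tmp_path, d, entities, name=f"s{seed}.pfb")
        before = payload_multisets(src)
        n_before = len(list(read_entities(src)))

        renamed = tmp_path / f"r{seed}.pfb"
        rename_node(src, renamed, d.nodes[1].name, "zz_renamed")
        counts = payload_multisets(renamed)
        counts[d.nodes[1].name] = counts.pop("zz_renamed", collections.Counter())
        assert counts == before
        assert len(list(read_entities(renamed))) == n_before

        retargeted = tmp_path / f"t{seed}.pfb"
        retarget_ontology(src, retargeted, {NCIT: CDISC})
        assert payload_multisets(retargeted) == before
        assert len(list(read_entities(retargeted))) == n_before
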
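"""`.bnet` parsing/compilation, format round-trips, the batch screen."""

import numpy as np
import pytest

from cyclesym import (SignedNetwork, compile_model, parse_bnet, read_bnet,
                      threshold_to_bnet, write_bnet)
from cyclesym.bnet import BnetParseError
from cyclesym.io import (load_network, read_motif_ids, read_network_json,
                         read_network_tsv, screen_models, write_motif_ids,
                         write_network_json, write_network_tsv)
from cyclesym.state_space import build_transition_map


class TestParsing:
    def test_single_identity_rule(self):
        net = compile_model(parse_bnet("v1, v1"))
        assert net.inputs == ((0,),)
        assert net.tables[0].tolist() == [0, 1]

    def test_negation_copy_model(self):
        net = compile_model(parse_bnet("a, !b\nb, a"))
        assert net.step(0b00) == 0b01  # a := !b = 1, b := a = 0

    def test_header_and_comments_skipped(self):
        text = "# model\ntargets, factors\na, a & a  # idempotent\n"
        model = parse_bnet(text)
        assert model.names == ("a",)

    def test_operator_precedence(self):
        # AND binds tighter than OR
        net = compile_model(parse_bnet("a, b | c & d\nb, 0\nc, 0\nd, 0"))
        table = net.tables[0]
        # inputs b,c,d in declaration order; pattern bits LSB-first
        def f(b, c, d):
            return table[b | (c << 1) | (d << 2)]
        for b in (0, 1):
            for c in (0, 1):
                for d in (0, 1):
                    assert f(b, c, d) == (b or (c and d))

    def test_malformed_line_reports_number(self):
        with pytest.raises(BnetParseError) as err:
            parse_bnet("a, a &")
        assert err.value.line == 1
        with pytest.raises(BnetParseError) as err:
            parse_bnet("a, a\nb, (a\n")
        assert err.value.line == 2

    def test_duplicate_target(self):
        with pytest.raises(BnetParseError, match="duplicate"):
            parse_bnet("a, 1\na, 0")

    def test_undeclared_reference(self):
        with pytest.raises(BnetParseError, match="undeclared"):
            parse_bnet("a, ghost")

    def test_empty_file(self):
        with pytest.raises(BnetParseError):
            parse_bnet("# only a comment\n")


class TestCompile:
    def test_constant_rules(self):
        net = compile_model(parse_bnet("a, 0\nb, 1"))
        assert net.inputs == ((), ())
        assert net.tables[0].tolist() == [0]
        assert net.tables[1].tolist() == [1]

    def test_tautology(self):
        net = compile_model(parse_bnet("a, b | !b\nb, 0"))
        assert net.tables[0].tolist() == [1, 1]

    def test_compiled_step_matches_expression_evaluation(self, rng):
        # dual-evaluation oracle: evaluate the ASTs directly on random states
        names = [f"g{i}" for i in range(6)]
        lines = []
        for i, name in enumerate(names):
            a, b, c = rng.choice(6, size=3, replace=False)
            lines.append(
                f"{name}, ({names[a]} & !{names[b]}) | {names[c]}")
        model = parse_bnet("\n".join(lines))
        net = compile_model(model)
        for _ in range(200):
            s = int(rng.integers(0, 64))
            env = {names[i]: (s >> i) & 1 for i in range(6)}
            expected = 0
            for i, expr in enumerate(model.exprs):
                expected |= expr.eval(env) << i
            assert net.step(s) == expected


class TestThresholdConversion:
    def test_zero_network_constant_zero(self):
        model = threshold_to_bnet(SignedNetwork(np.zeros((2, 2), dtype=int)))
        assert [e.unparse() for e in model.exprs] == ["0", "0"]

    def test_self_excitation_identity(self):
        model = threshold_to_bnet(SignedNetwork([[1]]))
        assert model.expression_str(0) == "v0"

    def test_mutual_excitation_dynamics_preserved(self, mutual_excitation):
        net = compile_model(threshold_to_bnet(mutual_excitation))
        assert build_transition_map(net).successor.tolist() == [0, 2, 1, 0]

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_roundtrip_reproduces_step_exactly(self, n, rng):
        signed = SignedNetwork(rng.integers(-1, 2, size=(n, n)))
        compiled = compile_model(threshold_to_bnet(signed))
        a = build_transition_map(signed).successor
        b = build_transition_map(compiled).successor
        assert (a == b).all()


class TestFormatsRoundTrip:
    def test_bnet_file_roundtrip_semantics(self, tmp_path, rng):
        model = threshold_to_bnet(SignedNetwork(rng.integers(-1, 2, (4, 4))))
        path = tmp_path / "model.bnet"
        write_bnet(model, path)
        again = read_bnet(path)
        assert again.names == model.names
        a = build_transition_map(compile_model(model)).successor
        b = build_transition_map(compile_model(again)).successor
        assert (a == b).all()

    def test_tsv_json_roundtrip(self, tmp_path, rng):
        net = SignedNetwork(rng.integers(-1, 2, size=(5, 5)))
        tsv, js = tmp_path / "net.tsv", tmp_path / "net.json"
        write_network_tsv(net, tsv)
        write_network_json(net, js)
        assert (read_network_tsv(tsv).W == net.W).all()
        assert (read_network_json(js).W == net.W).all()
        assert (load_network(tsv).W == load_network(js).W).all()

    def test_motif_id_list_roundtrip(self, tmp_path):
        ids = {"0" * 9, "+" * 9, "-0+" * 3}
        path = tmp_path / "motifs.txt"
        write_motif_ids(ids, path)
        assert read_motif_ids(path) == ids

    def test_unsupported_extension(self, tmp_path):
        path = tmp_path / "net.xyz"
        path.write_text("0")
        with pytest.raises(ValueError, match="unsupported"):
            load_network(path)


class TestScreen:
    def test_screen_mixed_directory(self, tmp_path, mutual_excitation):
        write_network_tsv(mutual_excitation, tmp_path / "mutual.tsv")
        (tmp_path / "toggle.bnet").write_text(
            "targets, factors\na, !b\nb, !a\n")
        df = screen_models(sorted(tmp_path.iterdir()), seed=0)
        df = df.set_index("model")
        assert df.loc["mutual", "p_sr"] == 0.5
        assert df.loc["mutual", "method"] == "exact"
        # the classic toggle switch is fully reflection-symmetric
        assert df.loc["toggle", "full_sym_fraction"] == 1.0

    def test_screen_uses_sampling_above_cap(self, tmp_path, mutual_excitation):
        write_network_tsv(mutual_excitation, tmp_path / "m.tsv")
        df = screen_models([tmp_path / "m.tsv"], cap=1, m=500, seed=1)
        assert df["method"].iloc[0] == "sampled"
        assert df["sample_count"].iloc[0] == 500
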
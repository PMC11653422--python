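"""Asset pool, similarity, difficulty scoring, and task-assembly tests."""
import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from citutor.errors import ContractError, PoolValidationError
from citutor.network import TASK_TYPES
from citutor.task_bank import (
    AssetPool,
    SoundAsset,
    TaskSpec,
    build_task,
    candidate_difficulty,
    generate_fixture_pool,
    load_pool,
    similarity,
    write_pool,
)


def make_asset(id="a1", asset_type="word", code="haus", rec=0.5, loud=0.5, conc=0.5,
               label=None, categories=()):
    return SoundAsset(
        id=id,
        asset_type=asset_type,
        label=label or code.capitalize(),
        categories=frozenset(categories),
        loudness=loud,
        recurrence=rec,
        concreteness=conc,
        length_syllables=1,
        phonetic_code=code,
    )


class TestManifests:
    def test_round_trip(self, tmp_path, pool_small):
        path = tmp_path / "pool.csv"
        write_pool(pool_small, path)
        reloaded = load_pool(path)
        assert len(reloaded) == len(pool_small)
        for a in pool_small:
            assert reloaded[a.id] == a

    def test_small_valid_csv(self):
        csv_text = (
            "id,asset_type,label,categories,loudness,recurrence,concreteness,"
            "length_syllables,phonetic_code\n"
            "a,sound,[pip],animal;nature,0.5,0.5,0.5,1,pip\n"
            "b,word,Maus,animal,0.2,0.9,0.8,1,maus\n"
            "c,sentence,Die Maus.,animal,0.5,0.1,0.3,4,di maus\n"
        )
        pool = load_pool(io.StringIO(csv_text))
        assert len(pool) == 3
        assert pool["a"].categories == {"animal", "nature"}

    def test_out_of_range_feature_names_row(self):
        csv_text = (
            "id,asset_type,label,categories,loudness,recurrence,concreteness,"
            "length_syllables,phonetic_code\n"
            "a,sound,[pip],animal,1.2,0.5,0.5,1,pip\n"
        )
        with pytest.raises(PoolValidationError, match="row 2"):
            load_pool(io.StringIO(csv_text))

    def test_duplicate_id_rejected(self):
        with pytest.raises(PoolValidationError, match="duplicate"):
            AssetPool([make_asset(id="x"), make_asset(id="x", code="maus")])

    def test_missing_column_rejected(self):
        with pytest.raises(PoolValidationError, match="phonetic_code"):
            load_pool(io.StringIO("id,asset_type\na,sound\n"))


class TestFixturePool:
    def test_study_sized_pool(self):
        pool = generate_fixture_pool(1053, seed=1)
        assert len(pool) == 1053

    def test_deterministic(self):
        a = generate_fixture_pool(120, seed=5)
        b = generate_fixture_pool(120, seed=5)
        assert sorted(x.id for x in a) == sorted(x.id for x in b)
        for x in a:
            assert b[x.id] == x

    def test_every_task_type_constructible(self):
        from citutor.tutor import select_task

        pool = generate_fixture_pool(1000, seed=2)
        for t in TASK_TYPES:
            task = select_task(pool, t, 0.5, [], seed=0)
            assert task.task_type == t

    def test_too_small_rejected(self):
        with pytest.raises(ContractError):
            generate_fixture_pool(49, seed=0)

    def test_passes_manifest_validation(self, tmp_path):
        pool = generate_fixture_pool(80, seed=3)
        path = tmp_path / "p.csv"
        write_pool(pool, path)
        assert len(load_pool(path)) == 80


class TestSimilarity:
    def test_identity(self):
        a = make_asset()
        assert similarity(a, a) == 1.0

    def test_disjoint_codes(self):
        a, b = make_asset(code="abc"), make_asset(id="a2", code="xyz")
        assert similarity(a, b) == 0.0

    def test_single_edit(self):
        a, b = make_asset(code="haus"), make_asset(id="a2", code="maus")
        assert similarity(a, b) == pytest.approx(0.75)

    def test_symmetric(self):
        a, b = make_asset(code="hausen"), make_asset(id="a2", code="maus")
        assert similarity(a, b) == similarity(b, a)

    def test_mixed_types_rejected(self):
        a = make_asset(asset_type="word")
        b = make_asset(id="a2", asset_type="sound", code="pip")
        with pytest.raises(ContractError):
            similarity(a, b)


class TestCandidateDifficulty:
    def test_sp_easiest_item(self):
        key = make_asset(asset_type="sound", loud=1.0, rec=1.0, conc=1.0)
        assert candidate_difficulty("SP", key) == 0.0

    def test_wd_different_trial_passes_similarity_through(self):
        key = make_asset(code="haus")
        dis = make_asset(id="a2", code="maus")
        assert candidate_difficulty("WD", key, [dis]) == pytest.approx(0.75)

    def test_wd_same_trial_uses_rarity(self):
        key = make_asset(rec=0.3)
        assert candidate_difficulty("WD", key, [], same_trial=True) == pytest.approx(0.7)

    def test_wi_blend_with_noise(self):
        key = make_asset(code="abcde", rec=0.5)
        sims = ["abcdx", "abcxy", "abxyz"]  # similarities 0.8, 0.6, 0.4
        dis = [make_asset(id=f"d{i}", code=c) for i, c in enumerate(sims)]
        got = candidate_difficulty("WI", key, dis, noise=True)
        assert got == pytest.approx(0.6 * 0.6 + 0.4 * 0.5 + 0.15)

    def test_wrong_arity_rejected(self):
        key = make_asset()
        with pytest.raises(ContractError):
            candidate_difficulty("WI", key, [make_asset(id="d1", code="x")])

    def test_monotone_in_distractor_similarity(self):
        key = make_asset(code="abcde", rec=0.5)
        near = [make_asset(id=f"n{i}", code=c) for i, c in enumerate(["abcdx", "abcdy", "abcdz"])]
        far = [make_asset(id=f"f{i}", code=c) for i, c in enumerate(["vwxyz", "uvwxy", "tuvwx"])]
        assert candidate_difficulty("WI", key, near) > candidate_difficulty("WI", key, far)

    @given(
        loud=st.floats(0, 1), rec=st.floats(0, 1), conc=st.floats(0, 1),
        noise=st.booleans(),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_difficulty_bounded(self, loud, rec, conc, noise):
        key = make_asset(asset_type="sound", loud=loud, rec=rec, conc=conc, code="pip")
        assert 0.0 <= candidate_difficulty("SP", key, noise=noise) <= 1.0


class TestBuildTask:
    def test_sp_silence_trial(self):
        key = make_asset(asset_type="sound", code="pip")
        task = build_task("SP", key, silence=True, seed=0)
        assert task.options == ("Yes", "No")
        assert task.correct_index == 1
        assert task.silence

    def test_sp_sounded_trial(self):
        task = build_task("SP", make_asset(asset_type="sound", code="pip"), seed=0)
        assert task.correct_index == 0

    def test_sc_category_membership_decides_answer(self):
        key = make_asset(asset_type="sound", code="pip", categories=("animal",))
        yes = build_task("SC", key, category="animal", seed=0)
        no = build_task("SC", key, category="traffic", seed=0)
        assert (yes.correct_index, no.correct_index) == (0, 1)

    def test_wd_same_and_different_trials(self):
        key = make_asset(code="haus")
        dis = make_asset(id="a2", code="maus")
        same = build_task("WD", key, same_trial=True, seed=0)
        diff = build_task("WD", key, [dis], seed=0)
        assert same.correct_index == 0 and diff.correct_index == 1

    def test_wi_contains_key_label_once(self):
        key = make_asset(code="haus")
        dis = [make_asset(id=f"d{i}", code=c) for i, c in enumerate(["maus", "laus", "baum"])]
        task = build_task("WI", key, dis, seed=9)
        assert len(task.options) == 4
        assert sum(1 for o in task.options if o == key.label) == 1
        assert task.options[task.correct_index] == key.label

    def test_option_order_deterministic(self):
        key = make_asset(code="haus")
        dis = [make_asset(id=f"d{i}", code=c) for i, c in enumerate(["maus", "laus", "baum"])]
        assert build_task("WI", key, dis, seed=4) == build_task("WI", key, dis, seed=4)

    def test_distractor_equal_to_key_rejected(self):
        key = make_asset(code="haus")
        with pytest.raises(ContractError):
            build_task("WD", key, [key], seed=0)

    def test_json_round_trip(self):
        key = make_asset(code="haus")
        dis = [make_asset(id=f"d{i}", code=c) for i, c in enumerate(["maus", "laus", "baum"])]
        task = build_task("WI", key, dis, noise=True, seed=2)
        assert TaskSpec.from_dict(task.to_dict()) == task
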
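"""Full-vector extraction contracts, cohort CSV round-trips and the CLI."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import nucleoqh as nq
from nucleoqh.io import RunConfig, read_cohort, write_cohort

from conftest import as_nucleus_set


def test_vector_length_and_family_partition(default_features):
    manifest = nq.canonical_manifest()
    assert len(default_features) == 216
    assert list(default_features) == manifest.names
    fams = {f: sum(1 for n in default_features if n.startswith(f)) for f in
            ("graph", "shape", "disorder", "cluster")}
    assert fams == {"graph": 51, "shape": 100, "disorder": 39, "cluster": 26}


def test_extraction_deterministic(default_field, default_features):
    again = nq.extract_all(as_nucleus_set(default_field))
    assert again == default_features


def _transformed(field: nq.GroundTruth, theta_deg: float, shift) -> nq.NucleusSet:
    theta = np.radians(theta_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shift = np.asarray(shift, dtype=float)
    return nq.NucleusSet(
        contours=[c @ rot.T + shift for c in field.contours],
        centroids=field.centroids @ rot.T + shift,
        mpp=field.mpp,
    )


def test_rigid_motion_invariance_of_all_features(default_field, default_features):
    """A 180-degree rotation plus translation preserves every pairwise
    distance and every axial orientation, so all 216 features must match."""
    vec = nq.extract_all(_transformed(default_field, 180.0, (250.0, -120.0)))
    for name, val in default_features.items():
        assert vec[name] == pytest.approx(val, rel=1e-6, abs=1e-9), name


def test_arbitrary_rotation_invariance_outside_disorder(default_field, default_features):
    """Under an arbitrary rotation the orientation bins shift, so only the
    disorder family may move (by bin-edge effects); the other 177 features
    are exactly invariant."""
    vec = nq.extract_all(_transformed(default_field, 33.0, (250.0, -120.0)))
    for name, val in default_features.items():
        if name.startswith("disorder:"):
            continue
        assert vec[name] == pytest.approx(val, rel=1e-6, abs=1e-9), name


def test_too_few_nuclei_error(default_field):
    tiny = nq.NucleusSet(
        contours=default_field.contours[:4],
        centroids=default_field.centroids[:4],
        mpp=default_field.mpp,
    )
    with pytest.raises(ValueError, match="nuclei"):
        nq.extract_all(tiny)


def test_transformer_interface(default_field):
    ext = nq.NucleusFeatureExtractor().fit([])
    X = ext.transform([as_nucleus_set(default_field)])
    assert X.shape == (1, 216)
    assert list(ext.get_feature_names_out()) == nq.canonical_manifest().names
    params = ext.get_params()
    assert params["min_nuclei"] == 10


# --- cohort CSV -----------------------------------------------------------


def _tiny_cohort_table(n: int = 4) -> pd.DataFrame:
    rng = np.random.default_rng(0)
    names = nq.canonical_manifest().names
    table = pd.DataFrame(rng.normal(size=(n, len(names))), columns=names)
    table.insert(0, "label", ["progressor", "non-progressor"] * (n // 2))
    table.insert(0, "patient_id", [f"P{i}" for i in range(n)])
    return table


def test_cohort_round_trip(tmp_path):
    table = _tiny_cohort_table()
    path = tmp_path / "cohort.csv"
    write_cohort(table, path)
    back = read_cohort(path)
    pd.testing.assert_frame_equal(back, table, check_exact=False, rtol=1e-12)


def test_cohort_wrong_feature_count(tmp_path):
    table = _tiny_cohort_table()
    path = tmp_path / "cohort.csv"
    write_cohort(table, path)
    df = pd.read_csv(path, skiprows=1)
    df.drop(columns=df.columns[-1]).to_csv(path, index=False)
    with pytest.raises(ValueError, match="feature count mismatch"):
        read_cohort(path)


def test_cohort_bad_label(tmp_path):
    table = _tiny_cohort_table()
    table.loc[1, "label"] = "mystery"
    path = tmp_path / "cohort.csv"
    write_cohort(table, path)
    with pytest.raises(ValueError, match="mystery"):
        read_cohort(path)


def test_cohort_version_mismatch_warns(tmp_path):
    table = _tiny_cohort_table()
    path = tmp_path / "cohort.csv"
    write_cohort(table, path)
    text = path.read_text().replace("manifest_version: 1.0", "manifest_version: 0.9")
    path.write_text(text)
    with pytest.warns(UserWarning, match="manifest version"):
        back = read_cohort(path)
    assert back.shape == table.shape


# --- config ---------------------------------------------------------------


def test_runconfig_rejects_unknown_keys(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("mpp: 0.5\nbogus_knob: 1\n")
    with pytest.raises(ValueError, match="bogus_knob"):
        RunConfig.from_yaml(path)
    path.write_text("mpp: 0.5\nn_iter: 10\n")
    cfg = RunConfig.from_yaml(path)
    assert cfg.mpp == 0.5 and cfg.n_iter == 10
    assert len(cfg.hash) == 12
    assert cfg.hash != RunConfig().hash


# --- nucleus set / ground truth JSON --------------------------------------


def test_nucleus_set_json_round_trip(tmp_path, default_field):
    from nucleoqh.io import read_nucleus_set, write_nucleus_set

    ns = as_nucleus_set(default_field)
    path = tmp_path / "nuclei.json"
    write_nucleus_set(ns, path)
    back = read_nucleus_set(path)
    assert back.mpp == ns.mpp
    assert np.allclose(back.centroids, ns.centroids)
    assert all(np.allclose(a, b) for a, b in zip(back.contours, ns.contours))


# --- CLI ------------------------------------------------------------------


def test_cli_pipeline_end_to_end(tmp_path):
    from click.testing import CliRunner

    from nucleoqh.cli import main

    runner = CliRunner()
    sim_dir = tmp_path / "sim"
    r = runner.invoke(main, ["simulate", "--out", str(sim_dir), "--n-per-class", "6",
                             "--seed", "5"])
    assert r.exit_code == 0, r.output
    assert (sim_dir / "cohort_manifest.csv").exists()

    cohort_csv = tmp_path / "cohort.csv"
    r = runner.invoke(main, ["extract", "--cohort-dir", str(sim_dir),
                             "--out", str(cohort_csv)])
    assert r.exit_code == 0, r.output

    sel_json = tmp_path / "selection.json"
    r = runner.invoke(main, ["select", "--cohort", str(cohort_csv), "--iters", "5",
                             "--auc-min", "0.0", "--seed", "1", "--out", str(sel_json)])
    assert r.exit_code == 0, r.output

    cfg_yaml = tmp_path / "cfg.yaml"
    cfg_yaml.write_text("cv_iterations: 3\n")
    model_json = tmp_path / "model.json"
    r = runner.invoke(main, ["train", "--cohort", str(cohort_csv),
                             "--selection", str(sel_json), "--seed", "1",
                             "--config", str(cfg_yaml), "--out", str(model_json)])
    assert r.exit_code == 0, r.output

    eval_json = tmp_path / "eval.json"
    r = runner.invoke(main, ["evaluate", "--train-cohort", str(cohort_csv),
                             "--test-cohort", str(cohort_csv),
                             "--model", str(model_json), "--out", str(eval_json)])
    assert r.exit_code == 0, r.output
    import json

    report = json.loads(eval_json.read_text())
    assert set(report["confusion"]) == {"tn", "fp", "fn", "tp"}
    assert 0.0 <= report["auc"] <= 1.0


def test_cli_segment_command(tmp_path, rendered_field):
    import imageio.v3 as iio
    import json
    from click.testing import CliRunner

    from nucleoqh.cli import main

    img, gt, cfg = rendered_field
    img_path = tmp_path / "field.png"
    iio.imwrite(img_path, img)
    out = tmp_path / "nuclei.json"
    runner = CliRunner()
    r = runner.invoke(main, ["segment", "--image", str(img_path), "--mpp", str(cfg.mpp),
                             "--out", str(out)])
    assert r.exit_code == 0, r.output
    payload = json.loads(out.read_text())
    assert len(payload["contours"]) == len(gt.contours)
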
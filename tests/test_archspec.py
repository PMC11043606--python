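"""Analytic parameter counting, shape propagation and spec plumbing."""

import numpy as np
import pytest

from btcnn.archspec import (
    BTCNNSpec,
    DenseSpec,
    GroupKind,
    GroupSpec,
    InvalidSpecError,
    MergeSpec,
    ParamCount,
    conv_group_param_count,
    count_broadening_params,
    count_classifier_params,
    count_merge_params,
    count_model_params,
    default_btcnn_spec,
    dense_param_count,
    ds_group_param_count,
    parameter_report,
    propagate_shapes,
    spec_from_yaml,
    spec_to_yaml,
    validate_spec,
)
from conftest import conv, ds, make_tiny_spec


@pytest.mark.parametrize(
    "c_in, k, total, trainable, non_trainable",
    [
        (1, 256, 3_584, 3_072, 512),  # first published group
        (32, 16, 4_688, 4_656, 32),  # post-merge groups
        (1, 1, 14, 12, 2),  # hand evaluation: 9+1+2 trainable, 2 moving stats
    ],
)
def test_conv_group_count(c_in, k, total, trainable, non_trainable):
    pc = conv_group_param_count(c_in, k)
    assert (pc.total, pc.trainable, pc.non_trainable) == (total, trainable, non_trainable)


@pytest.mark.parametrize(
    "c_in, k, total, non_trainable",
    [
        (128, 64, 10_304, 384),
        (64, 32, 3_104, 192),
        # hand evaluation: depthwise 9+1+4 = 14, pointwise 1+1+4 = 6
        (1, 1, 20, 4),
    ],
)
def test_ds_group_count(c_in, k, total, non_trainable):
    pc = ds_group_param_count(c_in, k)
    assert pc.total == total
    assert pc.non_trainable == non_trainable


@pytest.mark.parametrize(
    "n_in, n_out, total",
    [(2_304, 250, 576_250), (15, 4, 64), (1, 1, 2)],
)
def test_dense_count(n_in, n_out, total):
    pc = dense_param_count(n_in, n_out)
    assert pc.total == pc.trainable == total
    assert pc.non_trainable == 0


@pytest.mark.parametrize("bad", [(0, 4), (4, 0), (-1, 3)])
def test_nonpositive_arguments_rejected(bad):
    for fn in (conv_group_param_count, ds_group_param_count, dense_param_count):
        with pytest.raises(InvalidSpecError):
            fn(*bad)


def test_default_spec_grand_totals():
    pc = count_model_params(default_btcnn_spec())
    assert pc.total == 1_434_957
    assert pc.trainable == 1_430_733
    assert pc.non_trainable == 4_224


def test_default_spec_component_rows():
    """Per-component counts match the published per-row table (with the
    known 128-kernel row following the closed form, 295,552)."""
    pc = count_model_params(default_btcnn_spec())
    rows = pc.per_component
    assert rows["Convolution group"].total == 3_584
    assert rows["Convolution group 1"].total == 295_552
    assert rows["Depthwise convolution group"].total == 10_304
    assert rows["Depthwise convolution group 4"].total == 3_104
    assert rows["Convolution group 3"].total == 4_688
    assert rows["Dense + Dropout"].total == 576_250
    assert rows["Dense 1"].total == 62_750
    assert rows["Dense 3 + Dropout 1"].total == 25_100
    assert rows["Dense 9"].total == 64


def test_default_spec_subtotals():
    spec = default_btcnn_spec()
    assert count_classifier_params(spec).total == 755_469
    assert count_merge_params(spec).total == 18_752
    # broadening subtotal follows the closed form (sum of the group rows)
    assert count_broadening_params(spec).total == 660_736


def test_default_spec_structure():
    spec = default_btcnn_spec()
    kernels = [[g.kernels for g in level] for level in spec.levels]
    assert kernels == [[256], [128, 128], [64] * 4, [32] * 8]
    kinds = [{g.kind for g in level} for level in spec.levels]
    assert kinds == [
        {GroupKind.CONV},
        {GroupKind.CONV},
        {GroupKind.DEPTHWISE_SEPARABLE},
        {GroupKind.DEPTHWISE_SEPARABLE},
    ]
    assert [d.width for d in spec.classifier] == [250, 250, 250, 100, 100, 100, 60, 30, 15, 4]
    assert [d.dropout_rate for d in spec.classifier[:6]] == [0.2, 0, 0, 0.1, 0.05, 0]


def test_shape_trace_default_spec():
    trace = propagate_shapes(default_btcnn_spec())
    shapes = dict(trace.entries)
    assert shapes["Convolution group"] == (100, 100, 256)
    assert shapes["Convolution group 1"] == (50, 50, 128)
    assert shapes["Depthwise convolution group"] == (25, 25, 64)
    assert shapes["Depthwise convolution group 4"] == (12, 12, 32)  # 25 pools to 12
    assert shapes["Convolution group 3"] == (6, 6, 16)
    assert shapes["Concatenate"] == (6, 6, 64)
    assert trace.flat_length == 2_304


@pytest.mark.parametrize("size, expected", [(25, 12), (7, 3), (200, 100)])
def test_pooled_size_floors(size, expected):
    from btcnn.archspec import PoolDescriptor

    # only the first group pools, so small inputs survive the later stages
    no_pool = GroupSpec(GroupKind.CONV, 2, pool=PoolDescriptor((1, 1), (1, 1)))
    spec = BTCNNSpec(
        input_shape=(size, size, 1),
        levels=((conv(2),), (no_pool, no_pool)),
        merge=MergeSpec(group=no_pool),
        classifier=(DenseSpec(4, activation="softmax"),),
    )
    trace = propagate_shapes(spec)
    assert trace.shape_of("Convolution group")[0] == expected


def test_shape_collapse_is_an_error():
    deep = BTCNNSpec(
        input_shape=(200, 200, 1),
        levels=tuple(tuple(conv(2) for _ in range(2**i)) for i in range(9)),
        merge=MergeSpec(group=conv(2)),
        classifier=(DenseSpec(4, activation="softmax"),),
    )
    with pytest.raises(InvalidSpecError):
        propagate_shapes(deep)
    assert any("collapse" in v for v in validate_spec(deep))


def test_validate_default_spec_clean():
    assert validate_spec(default_btcnn_spec()) == []


def test_validate_flags_bad_kernels():
    spec = make_tiny_spec()
    broken = BTCNNSpec(
        input_shape=spec.input_shape,
        levels=((GroupSpec(GroupKind.CONV, 0),), spec.levels[1]),
        merge=spec.merge,
        classifier=spec.classifier,
    )
    violations = validate_spec(broken)
    assert violations and any("kernels" in v for v in violations)


def test_param_count_conservation():
    """Aggregate equals the sum of per-component entries, and total always
    splits into trainable + non-trainable."""
    pc = count_model_params(default_btcnn_spec())
    agg = ParamCount.zero()
    for part in pc.per_component.values():
        assert part.total == part.trainable + part.non_trainable
        agg = agg + part
    assert (agg.trainable, agg.non_trainable) == (pc.trainable, pc.non_trainable)


def test_non_trainable_is_twice_batchnormed_channels():
    rng = np.random.default_rng(42)
    for _ in range(20):
        widths = rng.integers(1, 9, size=3)
        kinds = rng.integers(0, 2, size=3)
        mk = lambda i: (conv if kinds[i] == 0 else ds)(int(widths[i]))  # noqa: E731
        spec = BTCNNSpec(
            input_shape=(16, 16, int(rng.integers(1, 4))),
            levels=((mk(0),), (mk(1), mk(1))),
            merge=MergeSpec(group=mk(2)),
            classifier=(DenseSpec(8), DenseSpec(4, activation="softmax")),
        )
        bn_channels = 0
        c_in = spec.input_shape[2]
        for level in spec.levels:
            outs = []
            for g in level:
                if g.kind is GroupKind.CONV:
                    bn_channels += g.kernels
                else:
                    bn_channels += c_in + g.kernels
                outs.append(g.kernels)
            c_in = outs[0]
        m = spec.merge.group
        if m.kind is GroupKind.CONV:
            bn_channels += m.kernels
        else:
            bn_channels += c_in + m.kernels
        assert count_model_params(spec).non_trainable == 2 * bn_channels


def test_shape_monotonicity():
    """Every component's spatial size is no larger than its inputs'."""
    from btcnn.archspec import enumerate_components

    for spec in (default_btcnn_spec(), make_tiny_spec()):
        comps = {c.label: c for c in enumerate_components(spec)}
        for c in comps.values():
            if not isinstance(c.output_shape, tuple):
                continue
            for parent in c.inputs:
                pshape = comps[parent].output_shape
                assert c.output_shape[0] <= pshape[0]
                assert c.output_shape[1] <= pshape[1]


def test_yaml_round_trip():
    for spec in (default_btcnn_spec(), make_tiny_spec()):
        assert spec_from_yaml(spec_to_yaml(spec)) == spec


def test_parameter_report_layout(tmp_path):
    spec = default_btcnn_spec()
    report = parameter_report(spec)
    assert list(report.columns) == [
        "component", "connected_to", "output_shape", "trainable", "non_trainable", "total",
    ]
    assert report["total"].sum() == 1_434_957
    row = report[report.component == "Convolution group"].iloc[0]
    assert row.output_shape == "100*100*256" and row.connected_to == "Input"
    path = tmp_path / "report.csv"
    report.to_csv(path, index=False)
    assert path.read_text().splitlines()[0].startswith("component,connected_to")
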
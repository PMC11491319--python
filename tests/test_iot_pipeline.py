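"""IoT adapter contracts and end-to-end pipeline orchestration."""

from dataclasses import replace

import numpy as np
import pytest

from lungcbo import classify, evaluate, iot, phantom, pipeline


def tiny_pipeline_config(n=16, seed=0, iot_enabled=False):
    return pipeline.PipelineConfig(
        source=pipeline.SourceConfig(
            n_phantoms=n,
            phantom=phantom.PhantomSpec(image_size=64, nodule_radius_px=8.0),
        ),
        segmentation=pipeline.SegmentConfig(population=12, iterations=15, min_area=10),
        densenet=classify.DenseNetConfig(input_size=32, initial_channels=8, growth_rate=4, seed=seed),
        train=classify.TrainConfig(epochs=1, batch_size=8, validation_fraction=0, seed=seed),
        iot=pipeline.IoTConfig(enabled=iot_enabled, min_interval_seconds=0),
        seed=seed,
    )


SAMPLE_METRICS = evaluate.MetricsReport(
    accuracy=0.9970, sensitivity=0.9943, specificity=0.9936, precision=0.97, auc=None
)


class TestChannelUpdate:
    def test_percent_formatting(self):
        update = iot.format_channel_update(SAMPLE_METRICS, {"accuracy": "field1"})
        assert update.fields == {"field1": 99.70}

    def test_duplicate_field_assignment_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            iot.format_channel_update(SAMPLE_METRICS, {"accuracy": "field1", "auc": "field1"})

    def test_empty_mapping_valid(self):
        update = iot.format_channel_update(SAMPLE_METRICS, {})
        assert update.fields == {}

    def test_undefined_metric_left_unmapped(self):
        update = iot.format_channel_update(SAMPLE_METRICS, {"auc": "field5", "accuracy": "field1"})
        assert "field5" not in update.fields

    def test_more_than_eight_fields_rejected(self):
        with pytest.raises(ValueError):
            iot.ChannelUpdate(api_key="", fields={f"field{i}": 1.0 for i in range(1, 9)} | {"field_x": 1.0})


class TestTransmit:
    def test_mock_round_trip(self):
        transport = iot.MockTransport()
        update = iot.format_channel_update(SAMPLE_METRICS, api_key="KEY")
        status = iot.transmit(update, transport)
        assert status.ok and status.status == "sent" and status.entry_id == 1
        assert len(transport.requests) == 1
        assert transport.requests[0].fields["field1"] == 99.70

    def test_rate_limit_reject_policy(self):
        clock_value = [0.0]
        tx = iot.Transmitter(iot.MockTransport(), min_interval_seconds=15,
                             policy="reject", clock=lambda: clock_value[0])
        update = iot.format_channel_update(SAMPLE_METRICS)
        assert tx.transmit(update).ok
        assert tx.transmit(update).status == "rate_limited"
        clock_value[0] = 20.0
        assert tx.transmit(update).ok

    def test_delay_policy_sleeps_instead(self):
        slept = []
        clock_value = [0.0]
        tx = iot.Transmitter(iot.MockTransport(), min_interval_seconds=10, policy="delay",
                             clock=lambda: clock_value[0], sleep=slept.append)
        update = iot.format_channel_update(SAMPLE_METRICS)
        tx.transmit(update)
        tx.transmit(update)
        assert slept == [10.0]

    def test_transport_failure_is_status_not_exception(self):
        status = iot.transmit(
            iot.format_channel_update(SAMPLE_METRICS), iot.MockTransport(fail=True)
        )
        assert not status.ok and status.status == "failed"


@pytest.fixture(scope="module")
def run_report():
    transport = iot.MockTransport()
    cfg = tiny_pipeline_config(n=16, seed=1, iot_enabled=True)
    report = pipeline.run_pipeline(cfg, transport=transport)
    return cfg, report, transport


class TestPipeline:
    def test_report_contract(self, run_report):
        _, report, _ = run_report
        n_test = sum(1 for _ in report["predictions"])
        assert n_test == 3  # largest-remainder of 16 at 70/10/20
        for pred in report["predictions"]:
            assert pred["message"] in ("Tumor is BENIGN", "Tumor is MALIGNANT")
            assert abs(sum(pred["probabilities"]) - 1) < 1e-6
        assert set(report["thresholds"]) == {p["image_id"] for p in report["predictions"]}

    def test_transmitted_fields_equal_report_metrics(self, run_report):
        cfg, report, transport = run_report
        assert report["transmission_status"] == "sent"
        assert len(transport.requests) == 1
        sent = transport.requests[0].fields
        expected = report["metrics_percent"]
        mapping = cfg.iot.field_mapping
        for metric, slot in mapping.items():
            if expected[metric] is not None:
                assert sent[slot] == expected[metric]

    def test_iot_disabled_means_zero_transport_calls(self):
        transport = iot.MockTransport()
        report = pipeline.run_pipeline(tiny_pipeline_config(n=12, seed=2), transport=transport)
        assert transport.requests == []
        assert report["transmission_status"] == "disabled"

    def test_failing_transport_does_not_break_run(self):
        report = pipeline.run_pipeline(
            tiny_pipeline_config(n=12, seed=3, iot_enabled=True),
            transport=iot.MockTransport(fail=True),
        )
        assert report["transmission_status"] == "failed"
        assert "metrics" in report

    def test_same_seed_reproduces_report(self):
        cfg = tiny_pipeline_config(n=12, seed=4)
        a = pipeline.run_pipeline(cfg)
        b = pipeline.run_pipeline(cfg)
        for key in ("thresholds", "predictions", "metrics", "confusion"):
            assert a[key] == b[key]

    def test_report_config_round_trip(self):
        # the recorded config alone re-executes the run
        cfg = tiny_pipeline_config(n=12, seed=5)
        report = pipeline.run_pipeline(cfg)
        cfg2 = pipeline.PipelineConfig.from_dict(report["config"])
        report2 = pipeline.run_pipeline(cfg2)
        assert report["metrics"] == report2["metrics"]
        assert report["thresholds"] == report2["thresholds"]

    def test_pretrained_weights_skip_training(self, tmp_path):
        model = classify.build_densenet(
            classify.DenseNetConfig(input_size=32, initial_channels=8, growth_rate=4, seed=0)
        )
        path = tmp_path / "weights.npz"
        classify.save_model(model, path)
        cfg = replace(tiny_pipeline_config(n=20, seed=6), pretrained_weights=str(path),
                      train_enabled=False)
        report = pipeline.run_pipeline(cfg)
        assert "training_history" not in report
        assert len(report["predictions"]) == 4  # test split of 20 at 70/10/20
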
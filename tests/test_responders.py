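"""Abundant / increased / treatment-specific filtering rules."""

import numpy as np
import pandas as pd
import pytest

from bloomtrack import (
    PipelineConfig,
    SimConfig,
    abundant_asvs,
    increased_votus,
    simulate_microcosm,
    treatment_specific_asvs,
    treatment_specific_votus,
)
from bloomtrack.pipeline import detect_responders


class TestAbundantAsvs:
    def test_exactly_the_planted_risers(self, toy_riser_table):
        table, md = toy_riser_table
        res = abundant_asvs(table, md, "CIF")
        assert set(res.index[res["abundant"]]) == {f"riser{i}" for i in range(5)}

    def test_rank21_in_one_replicate_excluded(self, toy_riser_table):
        table, md = toy_riser_table
        # push a riser below rank 20 in flask III on every day >= 1
        table = table.copy()
        iii = [s for s in table.columns if md.at[s, "replicate"] == "III"
               and int(md.at[s, "day"]) >= 1]
        table.loc["riser0", iii] = 1.0
        res = abundant_asvs(table, md, "CIF")
        assert not res.at["riser0", "abundant"]
        assert res.at["riser1", "abundant"]

    def test_constant_top_feature_fails_fold_rule(self, toy_riser_table):
        table, md = toy_riser_table
        table = table.copy()
        table.loc["bg19"] = 1e6  # always rank 1, never doubles
        res = abundant_asvs(table, md, "CIF")
        assert res.at["bg19", "rank_pass"]
        assert not res.at["bg19", "fold_pass"]
        assert not res.at["bg19", "abundant"]

    def test_zero_day0_passes_fold_when_later_positive(self, toy_riser_table):
        table, md = toy_riser_table
        table = table.copy()
        d0 = [s for s in table.columns if int(md.at[s, "day"]) == 0]
        table.loc["riser2", d0] = 0.0
        res = abundant_asvs(table, md, "CIF")
        assert res.at["riser2", "abundant"]

    def test_missing_day0_raises(self, toy_riser_table):
        table, md = toy_riser_table
        keep = [s for s in table.columns if int(md.at[s, "day"]) != 0]
        with pytest.raises(ValueError, match="day-0"):
            abundant_asvs(table[keep], md.loc[keep], "CIF")


class TestTreatmentSpecificAsvs:
    def _abundant(self, control=(), cif=(), hif=()):
        def frame(names):
            all_feats = sorted(set(control) | set(cif) | set(hif))
            return pd.DataFrame(
                {"rank_pass": True, "fold_pass": True,
                 "abundant": [f in names for f in all_feats]},
                index=all_feats,
            )
        return {"control": frame(control), "CIF": frame(cif), "HIF": frame(hif)}

    def _lefse(self, sig_for):
        rows = []
        for feat, cls in sig_for.items():
            rows.append(
                {"feature_id": feat, "kw_p": 0.001, "subclass_consistent": True,
                 "lda_log_score": 4.0, "enriched_class": cls,
                 "significant": bool(cls)}
            )
        return pd.DataFrame(rows).set_index("feature_id")

    def test_abundant_in_both_lysates_excluded(self):
        ab = self._abundant(cif=["f1"], hif=["f1"])
        res = treatment_specific_asvs(ab, self._lefse({"f1": "CIF"}))
        assert res["CIF"].empty and res["HIF"].empty

    def test_cif_only_and_enriched_is_specific(self):
        ab = self._abundant(cif=["f1"])
        res = treatment_specific_asvs(ab, self._lefse({"f1": "CIF"}))
        assert list(res["CIF"].index) == ["f1"]

    def test_nonsignificant_lefse_excluded(self):
        ab = self._abundant(cif=["f1"])
        res = treatment_specific_asvs(ab, self._lefse({"f1": ""}))
        assert res["CIF"].empty

    def test_abundant_in_control_excluded(self):
        ab = self._abundant(control=["f1"], cif=["f1"])
        res = treatment_specific_asvs(ab, self._lefse({"f1": "CIF"}))
        assert res["CIF"].empty


class TestIncreasedVotus:
    def _particle_table(self, microcosm_metadata, scale, rng):
        """One vOTU rising 100-fold after day 0, peak at `scale` particles/mL."""
        md = microcosm_metadata
        cif = [s for s in md.index if md.at[s, "treatment"] == "CIF"]
        vals = {
            s: scale * (0.01 if int(md.at[s, "day"]) == 0 else 1.0)
            * rng.lognormal(0, 0.05)
            for s in cif
        }
        return pd.DataFrame([vals], index=["v0"]), md

    def test_sub_threshold_peak_discarded_despite_fold_change(
        self, microcosm_metadata, rng
    ):
        table, md = self._particle_table(microcosm_metadata, scale=90.0, rng=rng)
        res = increased_votus(table, md, "CIF", PipelineConfig(), seed=0)
        # the 100-fold rise passes the rank gates but a sub-burst-size peak
        # can never be called increased
        assert res.at["v0", "kw_p"] < 0.05
        assert res.at["v0", "subclass_consistent"]
        assert res.at["v0", "peak_particles_per_ml"] < 100
        assert not res.at["v0", "increased"]

    def test_above_threshold_peak_retained(self, microcosm_metadata, rng):
        table, md = self._particle_table(microcosm_metadata, scale=1e5, rng=rng)
        res = increased_votus(table, md, "CIF", PipelineConfig(), seed=0)
        assert res.at["v0", "increased"]

    def test_flat_high_abundance_not_significant(self, microcosm_metadata, rng):
        md = microcosm_metadata
        cif = [s for s in md.index if md.at[s, "treatment"] == "CIF"]
        vals = {s: 1e4 * rng.lognormal(0, 0.2) for s in cif}
        table = pd.DataFrame([vals], index=["v0"])
        res = increased_votus(table, md, "CIF", PipelineConfig(), seed=0)
        assert not res.at["v0", "increased"]

    def test_planted_burst_votus_recovered(self, sim, sim_responders):
        _, truth = sim
        inc = sim_responders["votu_increased"]["CIF"]
        planted = truth.votu.index[
            (truth.votu["responder_class"] == "CIF") & ~truth.votu["lysogenic"]
        ]
        recovered = [v for v in planted if inc.at[v, "increased"]]
        assert len(recovered) >= 0.9 * len(planted)


class TestTreatmentSpecificVotus:
    def _increased(self, control=(), cif=(), hif=()):
        feats = sorted(set(control) | set(cif) | set(hif))
        out = {}
        for t, names in [("control", control), ("CIF", cif), ("HIF", hif)]:
            out[t] = pd.DataFrame(
                {"increased": [f in names for f in feats]}, index=feats
            )
        return out

    def test_categories(self):
        res = treatment_specific_votus(
            self._increased(
                control=["v_all"], cif=["v_all", "v_both", "v_cif"],
                hif=["v_all", "v_both", "v_hif"],
            )
        )
        assert res.at["v_all", "category"] == "all"
        assert res.at["v_both", "category"] == "both"
        assert res.at["v_cif", "category"] == "CIF-specific"
        assert res.at["v_hif", "category"] == "HIF-specific"

    def test_control_only_is_not_specific(self):
        res = treatment_specific_votus(self._increased(control=["v0"]))
        assert res.at["v0", "category"] == "other"


def test_recovery_monotone_in_effect_size():
    """Raising the planted enrichment never removes a recovered planted
    responder (fixed seed)."""
    cfg_lo = SimConfig(responder_enrichment=10.0)
    cfg_hi = SimConfig(responder_enrichment=20.0)
    found = {}
    for name, cfg in [("lo", cfg_lo), ("hi", cfg_hi)]:
        ds, truth = simulate_microcosm(cfg, seed=11)
        res = detect_responders(ds, config=PipelineConfig(), seed=11)
        planted = set(truth.asv.index[truth.asv["responder_class"] != "none"])
        got = set(res["specific_asvs"]["CIF"].index) | set(res["specific_asvs"]["HIF"].index)
        found[name] = got & planted
    assert found["lo"] <= found["hi"]
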
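{
  "root": "autoproc_summary",
  "required_children": {
    "program": {},
    "branch": {
      "min": 1,
      "required_attributes": ["friedel_merged"],
      "required_children": {
        "n_rejected": {},
        "resolution_limit": {
          "required_children": {"d_min": {}, "rule": {}}
        },
        "shells": {
          "required_children": {
            "shell": {
              "min": 1,
              "required_children": {
                "d_max": {}, "d_min": {}, "n_obs": {}, "n_unique": {},
                "n_theoretical": {}, "completeness": {},
                "mean_i_over_sigma": {}, "r_merge": {}, "r_meas": {},
                "multiplicity": {}
              }
            }
          }
        },
        "overall": {
          "required_children": {"shell": {"min": 1}}
        }
      }
    }
  }
}
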
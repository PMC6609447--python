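{
 "synthetic_blue_light_hazard.csv": "01d198733ff4fe716423634241ac5a17fd73db602d09aa3f0acbdd6d26e29a36",
 "synthetic_l_cone_opic.csv": "1c7e22fee368a9bd0841de5e56556018e67b021e531a4b8aceae3eb4d52177b9",
 "synthetic_m_cone_opic.csv": "37cd863ca5bb53118347828a2e90a0c6ef68596cf27fa37192280fd395be6d1d",
 "synthetic_melanopic.csv": "98ff839c7eb48c37f92a1ee37980a20539da16154f58dc4b3a537d0a26438d7b",
 "synthetic_photopic_V.csv": "0021a4e114dff6e495747201a6048109c391c8280a6e8bd753df5acfa86f79f8",
 "synthetic_rhodopic.csv": "8c38c788adf0cd9f566a72b54723c16a961992dc9617c8a6c0723d7d95ea72eb",
 "synthetic_s_cone_opic.csv": "7d76943254dddf3a3c7f6ca8e4b6ad6982eea6567a360911bd559d9f8b3e0d0d"
}
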
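{
 "version": "1.0",
 "families": [
  {
   "family_id": "dxs",
   "pathway_stage": "MEP",
   "canonical_bgc_member": false,
   "canonical_rank": null,
   "similarity_threshold": 50.0,
   "query_label": "QRY_DXS"
  },
  {
   "family_id": "dxr",
   "pathway_stage": "MEP",
   "canonical_bgc_member": false,
   "canonical_rank": null,
   "similarity_threshold": 50.0,
   "query_label": "QRY_DXR"
  },
  {
   "family_id": "ispD",
   "pathway_stage": "MEP",
   "canonical_bgc_member": false,
   "canonical_rank": null,
   "similarity_threshold": 50.0,
   "query_label": "QRY_ISPD"
  },
  {
   "family_id": "ispE",
   "pathway_stage": "MEP",
   "canonical_bgc_member": false,
   "canonical_rank": null,
   "similarity_threshold": 50.0,
   "query_label": "QRY_ISPE"
  },
  {
   "family_id": "ispF",
   "pathway_stage": "MEP",
   "canonical_bgc_member": false,
   "canonical_rank": null,
   "similarity_threshold": 50.0,
   "query_label": "QRY_ISPF"
  },
  {
   "family_id": "ispDF",
   "pathway_stage": "MEP",
   "canonical_bgc_member": false,
   "canonical_rank": null,
   "similarity_threshold": 50.0,
   "query_label": "QRY_ISPDF"
  },
  {
   "family_id": "ispG",
   "pathway_stage": "MEP",
   "canonical_bgc_member": false,
   "canonical_rank": null,
   "similarity_threshold": 50.0,
   "query_label": "QRY_ISPG"
  },
  {
   "family_id": "ispH",
   "pathway_stage": "MEP",
   "canonical_bgc_member": false,
   "canonical_rank": null,
   "similarity_threshold": 50.0,
   "query_label": "QRY_ISPH"
  },
  {
   "family_id": "ispA",
   "pathway_stage": "MEP",
   "canonical_bgc_member": false,
   "canonical_rank": null,
   "similarity_threshold": 50.0,
   "query_label": "QRY_ISPA"
  },
  {
   "family_id": "hpnA",
   "pathway_stage": "accessory",
   "canonical_bgc_member": true,
   "canonical_rank": 0,
   "similarity_threshold": 50.0,
   "query_label": "QRY_HPNA"
  },
  {
   "family_id": "hpnB",
   "pathway_stage": "accessory",
   "canonical_bgc_member": true,
   "canonical_rank": 1,
   "similarity_threshold": 50.0,
   "query_label": "QRY_HPNB"
  },
  {
   "family_id": "hpnC",
   "pathway_stage": "squalene",
   "canonical_bgc_member": true,
   "canonical_rank": 2,
   "similarity_threshold": 50.0,
   "query_label": "QRY_HPNC"
  },
  {
   "family_id": "hpnD",
   "pathway_stage": "squalene",
   "canonical_bgc_member": true,
   "canonical_rank": 3,
   "similarity_threshold": 50.0,
   "query_label": "QRY_HPND"
  },
  {
   "family_id": "hpnE",
   "pathway_stage": "squalene",
   "canonical_bgc_member": true,
   "canonical_rank": 4,
   "similarity_threshold": 50.0,
   "query_label": "QRY_HPNE"
  },
  {
   "family_id": "shc",
   "pathway_stage": "core_BHPD",
   "canonical_bgc_member": true,
   "canonical_rank": 5,
   "similarity_threshold": 50.0,
   "query_label": "QRY_SHC"
  },
  {
   "family_id": "hpnG",
   "pathway_stage": "core_BHPD",
   "canonical_bgc_member": true,
   "canonical_rank": 6,
   "similarity_threshold": 50.0,
   "query_label": "QRY_HPNG"
  },
  {
   "family_id": "hpnH",
   "pathway_stage": "core_BHPD",
   "canonical_bgc_member": true,
   "canonical_rank": 7,
   "similarity_threshold": 50.0,
   "query_label": "QRY_HPNH"
  },
  {
   "family_id": "hpnI",
   "pathway_stage": "CE_branch",
   "canonical_bgc_member": true,
   "canonical_rank": 8,
   "similarity_threshold": 50.0,
   "query_label": "QRY_HPNI"
  },
  {
   "family_id": "hpnJ",
   "pathway_stage": "CE_branch",
   "canonical_bgc_member": true,
   "canonical_rank": 9,
   "similarity_threshold": 50.0,
   "query_label": "QRY_HPNJ"
  },
  {
   "family_id": "hpnK",
   "pathway_stage": "CE_branch",
   "canonical_bgc_member": true,
   "canonical_rank": 10,
   "similarity_threshold": 50.0,
   "query_label": "QRY_HPNK"
  },
  {
   "family_id": "hpnL",
   "pathway_stage": "accessory",
   "canonical_bgc_member": true,
   "canonical_rank": 11,
   "similarity_threshold": 50.0,
   "query_label": "QRY_HPNL"
  },
  {
   "family_id": "hpnM",
   "pathway_stage": "transport",
   "canonical_bgc_member": true,
   "canonical_rank": 12,
   "similarity_threshold": 50.0,
   "query_label": "QRY_HPNM"
  },
  {
   "family_id": "hpnN",
   "pathway_stage": "transport",
   "canonical_bgc_member": true,
   "canonical_rank": 13,
   "similarity_threshold": 50.0,
   "query_label": "QRY_HPNN"
  },
  {
   "family_id": "hpnO",
   "pathway_stage": "amino_branch",
   "canonical_bgc_member": false,
   "canonical_rank": null,
   "similarity_threshold": 50.0,
   "query_label": "QRY_HPNO"
  },
  {
   "family_id": "hpnP",
   "pathway_stage": "methylation",
   "canonical_bgc_member": false,
   "canonical_rank": null,
   "similarity_threshold": 55.0,
   "query_label": "QRY_HPNP"
  },
  {
   "family_id": "hpnR",
   "pathway_stage": "methylation",
   "canonical_bgc_member": false,
   "canonical_rank": null,
   "similarity_threshold": 50.0,
   "query_label": "QRY_HPNR"
  },
  {
   "family_id": "ths",
   "pathway_stage": "tetrahymanol",
   "canonical_bgc_member": false,
   "canonical_rank": null,
   "similarity_threshold": 50.0,
   "query_label": "QRY_THS"
  },
  {
   "family_id": "desat",
   "pathway_stage": "desaturase",
   "canonical_bgc_member": false,
   "canonical_rank": null,
   "similarity_threshold": 50.0,
   "query_label": "QRY_DESAT"
  },
  {
   "family_id": "hpnX",
   "pathway_stage": "desaturase",
   "canonical_bgc_member": false,
   "canonical_rank": null,
   "similarity_threshold": 50.0,
   "query_label": "QRY_HPNX"
  },
  {
   "family_id": "aceE",
   "pathway_stage": "accessory",
   "canonical_bgc_member": false,
   "canonical_rank": null,
   "similarity_threshold": 50.0,
   "query_label": "QRY_ACEE"
  }
 ]
}
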
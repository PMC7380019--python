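; synthetic S-motif seed alignment (fixture, not a published motif model)
>S_seed_1
VVTLWTLIDGRVKACVDDMAMELFMQQVEHG
>S_seed_2
GVTLWTLIDGRNKACVVDMAMELFMQQVEHM
>S_seed_3
VVMLWTLIDGRVAACVDDMMMELGMQQVEHG
>S_seed_4
VVTLWTLIMGRVKCCVDDMAMELFMIQVLHG
>S_seed_5
VVTLWTLIDGRVKACVDDMANWLGMRQVEHG
>S_seed_6
VVTLITLIDGRVKACVDDMCMERRMQQVEHG
>S_seed_7
VVTLWTLIDGRVKACVDDMQMELNMQQAEAG
>S_seed_8
VVTLWTLFDGRVKACVDVMAMELAMQQVEHD
>S_seed_9
VVTLWTLIDGRVKACVDDHAMELGGQQVEHA
>S_seed_10
VSTLWTLIDGRMKACVDDMAMELAMQQVEYG
>S_seed_11
VVTLITLIDGRYKALVDDMAMELFMQQVNHG
>S_seed_12
VVTLWTLIDGRNKACVDDMAMECLMQQVEHV
>S_seed_13
VVTLWTPIYGRVKACVDDLAMELGMQQVEHG
>S_seed_14
MVTCWTLIDGRVKACVDDMEMELFMQQVLHG
>S_seed_15
VVTLLTTIDGRVKACRDDMAMHLFMQQVEHG
>S_seed_16
VVTLWHLINGRVKACQRDMAMELFMQQVEHG
>S_seed_17
VYTLWTLIDGRVKACVCVMAMELTMQQVEHG
>S_seed_18
VVTLWTLCDGRVCAQVDDQAMELFMQQVEHG
>S_seed_19
VVTLWTLLDGRPKACNDDMAMELFMQQMEHG
>S_seed_20
IVTPWTLIDGRVKACVDDMAMRLFMYQVEHG
>S_seed_21
VVTLWTLMNGRVKFCVDDMAMELFMQGVEHG
>S_seed_22
VVTLNTLIDSRVKACVDDDAMELFMQQVEHP
>S_seed_23
VVTLWTLIDGRVKECWDDMMMSLFMQQVEHG
>S_seed_24
VVTLWTLIDGRSKNCVDDMAMELFWQWVEHG
>S_seed_25
VDTLWTLIDGRVKACVDEMRSELFMQQVEHG
>S_seed_26
VFTLWTLHDGRVKACYDDMAMELTMQQVEHG
>S_seed_27
VTTLWTLIAGFVKACVDDMAMELFMQDVEHG
>S_seed_28
VVCLWTGIDGRDKACVDDMAMELFYQQVEHG
>S_seed_29
VVTEWTQIDGRQKACVDDMAMELFMQQVEMG
>S_seed_30
RVTLWTLIDGRVKACFDDMAMCLFMQAVEHG
>S_seed_31
DVFLWTLIDGQVKACVDDMAMELFMQQEEHG
>S_seed_32
VVTLVTAIDGRVKACVDDMAIELFMQQVEAG
>S_seed_33
VNTGWTLIDGRQKAFVDDMAMELFMQQVEHG
>S_seed_34
VWTLLTLIDGRVKACVFQMAMELFMQQVEHG
>S_seed_35
YVTLWTSIDGRHKACVADMAMELFMQQVEHG
>S_seed_36
VVTLWTLIENRRKACVDDLAMELFMQQVEHG
>S_seed_37
VVILWDLIDARVKACVDDMAMELMMQQVEHG
>S_seed_38
VVTLWTLIDGRVKACIDDMAMWPFMQQVQHG
>S_seed_39
MVTLWTLKDLRVKACVDDMAFELFMQQVEHG
>S_seed_40
VVTLWTLADGHVKACVDDMAMELVMQEVEHG
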
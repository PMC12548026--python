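name	source	data_format	technology	field_class	sage_only	table_delimiter	duplicate_of	in_dataset
characteristics	documented	semi_structured	both	biological	0	0		1
description	documented	unstructured	both	biological	0	0		1
growth_protocol	documented	unstructured	both	biological	0	0		1
molecule	documented	structured	both	biological	0	0		1
organism	documented	structured	both	biological	0	0		1
source_name	documented	unstructured	both	biological	0	0		1
treatment_protocol	documented	unstructured	both	biological	0	0		1
contact_city	documented	structured	both	database	0	0		1
contact_department	documented	structured	both	database	0	0		1
contact_email	documented	structured	both	database	0	0		1
contact_fax	documented	structured	both	database	0	0		1
contact_institute	documented	structured	both	database	0	0		1
contact_name	documented	structured	both	database	0	0		1
contact_phone	documented	structured	both	database	0	0		1
contact_web_link	documented	structured	both	database	0	0		1
data_row_count	documented	structured	both	database	0	0		1
geo_accession	documented	structured	both	database	0	0		1
last_update_date	documented	structured	both	database	0	0		1
status	documented	structured	both	database	0	0		1
submission_date	documented	structured	both	database	0	0		1
title	documented	unstructured	both	database	0	0		1
biomaterial_provider	documented	structured	both	technical	0	0		1
channel_count	documented	structured	both	technical	0	0		1
data_processing	documented	unstructured	both	technical	0	0		1
extract_protocol	documented	unstructured	both	technical	0	0		1
hyb_protocol	documented	unstructured	microarray	technical	0	0		1
label	documented	structured	microarray	technical	0	0		1
label_protocol	documented	unstructured	microarray	technical	0	0		1
platform_id	documented	structured	both	technical	0	0		1
scan_protocol	documented	unstructured	microarray	technical	0	0		1
supplementary_file	documented	structured	both	technical	0	0		1
type	documented	structured	both	technical	0	0		1
taxid	reported_in_study	structured	both	biological	0	0		1
contact_address	reported_in_study	structured	both	database	0	0		1
contact_country	reported_in_study	structured	both	database	0	0		1
contact_laboratory	reported_in_study	structured	both	database	0	0		1
contact_state	reported_in_study	structured	both	database	0	0		1
contact_zip/postal_code	reported_in_study	structured	both	database	0	0		1
relation	reported_in_study	structured	both	database	0	0		1
series_id	reported_in_study	structured	both	database	0	0		1
barcode	reported_in_study	structured	rnaseq	technical	0	0		1
instrument_model	reported_in_study	structured	rnaseq	technical	0	0		1
library_selection	reported_in_study	structured	rnaseq	technical	0	0		1
library_source	reported_in_study	structured	rnaseq	technical	0	0		1
library_strategy	reported_in_study	structured	rnaseq	technical	0	0		1
anchor	documented	structured	both	technical	1	0		0
tag_count	documented	structured	both	technical	1	0		0
tag_length	documented	structured	both	technical	1	0		0
table_begin	documented	structured	both	database	0	1		0
table	documented	structured	both	database	0	1		0
table_end	documented	structured	both	database	0	1		0
geo_accession_2	documented	structured	both	database	0	0	geo_accession	0
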
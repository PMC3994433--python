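<?xml version="1.0" encoding="UTF-8"?>
<!-- Flashdump dialect, format_version 1.0.

     A flashdump is the XML export of the MEFI parameter libraries held by
     all device control units (DCUs) of the facility: a header with export
     metadata and integrity fields, followed by one dcu element per control
     unit carrying its parameter sets keyed by MEFI indices (and, for
     gantry-room devices, an angle-node index). -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:simpleType name="dumpType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="flash"/>
      <xs:enumeration value="ram"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="utcInstant">
    <xs:restriction base="xs:string">
      <xs:pattern value="[0-9]{4}-[0-9]{2}-[0-9]{2}T[0-9]{2}:[0-9]{2}:[0-9]{2}Z"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="sha256Hex">
    <xs:restriction base="xs:string">
      <xs:pattern value="[0-9a-f]{64}"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="flashdump">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="header">
          <xs:complexType>
            <xs:attribute name="dump_type" type="dumpType" use="required"/>
            <xs:attribute name="export_timestamp" type="utcInstant" use="required"/>
            <xs:attribute name="facility_id" type="xs:string" use="required"/>
            <xs:attribute name="dcu_count" type="xs:nonNegativeInteger" use="required"/>
            <xs:attribute name="payload_checksum" type="sha256Hex" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="body">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="dcu" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="setting" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="param" minOccurs="0" maxOccurs="unbounded">
                            <xs:complexType>
                              <xs:attribute name="name" type="xs:string" use="required"/>
                              <xs:attribute name="value" type="xs:string" use="required"/>
                              <xs:attribute name="unit" type="xs:string"/>
                            </xs:complexType>
                          </xs:element>
                        </xs:sequence>
                        <xs:attribute name="species" type="xs:string" use="required"/>
                        <xs:attribute name="e" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="f" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="i" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="node" type="xs:nonNegativeInteger"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                  <xs:attribute name="id" type="xs:string" use="required"/>
                  <xs:attribute name="name" type="xs:string" use="required"/>
                  <xs:attribute name="class" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="format_version" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
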